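"""Score molecular environments against experimental shift distributions.

Each candidate environment (one molecule in one frame, with its
surroundings) carries a set of predicted chemical shifts.  For every
assigned site the probability that a draw from the experimental
Gaussian N(mu, sigma^2) lies farther from mu than the predicted shift
is computed (a two-sided tail probability); the environment's p-value
is the geometric mean of these per-site probabilities.  The "NMR set"
is the top-N environments by p-value; the "MD set" is everything.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc

from .spectra import ShiftDistribution

__all__ = [
    "EnvironmentShifts",
    "EnvironmentScore",
    "EnsembleSelection",
    "shift_probability",
    "score_environment",
    "rank_and_select",
    "score_dataset",
    "read_predictions",
    "write_scores",
]

#: Probability floor applied inside the log-space geometric mean.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class EnvironmentShifts:
    """Predicted per-atom shifts (ppm) of one molecular environment."""

    env_id: tuple  # (run_id, frame_index, molecule_index)
    shifts: dict  # atom_label -> ppm

    def __post_init__(self):
        for label, val in self.shifts.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite predicted shift for {label} in {self.env_id}")


@dataclass(frozen=True)
class EnvironmentScore:
    env_id: tuple
    per_atom_p: dict
    pvalue: float


@dataclass
class EnsembleSelection:
    """Ranked environments, the selected NMR set and the full MD set."""

    ranked: list  # env_ids, best first
    nmr_set: list
    md_set: list
    n_selected: int
    min_selected_pvalue: float
    pvalues: dict = field(default_factory=dict)  # env_id -> pvalue

    def summary(self) -> dict:
        p = np.array([self.pvalues[e] for e in self.md_set])
        return {
            "n_environments": len(self.md_set),
            "n_selected": self.n_selected,
            "min_selected_pvalue": self.min_selected_pvalue,
            "median_pvalue": float(np.median(p)) if p.size else math.nan,
            "min_pvalue": float(p.min()) if p.size else math.nan,
        }


def shift_probability(predicted, dist: ShiftDistribution):
    """Two-sided Gaussian tail probability of a predicted shift.

    Returns erfc(|predicted - mu| / (sigma * sqrt(2))): the probability
    that a draw from the experimental distribution N(mu, sigma^2)
    deviates from mu by more than the predicted shift does.  Equals 1
    at zero deviation and decays monotonically with |predicted - mu|.
    """
    predicted = np.asarray(predicted, dtype=float)
    if not np.all(np.isfinite(predicted)):
        raise ValueError("non-finite predicted shift")
    z = np.abs(predicted - dist.mu) / (dist.sigma * math.sqrt(2.0))
    out = erfc(z)
    return float(out) if out.ndim == 0 else out


def _distribution_index(dists):
    """Map every member label (including lumped ones) to its distribution."""
    index = {}
    for d in dists:
        for label in d.members:
            if label in index:
                raise ValueError(f"atom label {label} appears in more than one distribution")
            index[label] = d
    return index


def _equivalent_groups(labels):
    """Group equivalent-proton labels: H12a/H12b -> H12. Other labels stand alone."""
    groups = {}
    for label in labels:
        base = label[:-1] if label[-1] in "ab" and label[0] == "H" else label
        groups.setdefault(base, []).append(label)
    return groups


def score_environment(env, dists, atom_subset=None, *, average_equivalent=True):
    """Score one environment: per-site tail probabilities and their geometric mean.

    Parameters
    ----------
    env : EnvironmentShifts
    dists : iterable of ShiftDistribution
        Experimental distributions; lumped members share their peak.
    atom_subset : list of str, optional
        Site labels to score (defaults to every label with a
        distribution).  Labels may address lumped members directly.
    average_equivalent : bool
        Arithmetically average predicted shifts of equivalent protons
        (labels differing only by an a/b suffix) before scoring, as
        fast exchange averages them experimentally.

    Returns
    -------
    EnvironmentScore
        ``pvalue`` is computed in log space with a 1e-300 floor.
    """
    index = _distribution_index(dists)
    if atom_subset is None:
        atom_subset = sorted(index)

    targets = {}
    if average_equivalent:
        for base, members in _equivalent_groups(atom_subset).items():
            key = base if len(members) > 1 else members[0]
            targets[key] = members
    else:
        targets = {label: [label] for label in atom_subset}

    per_atom_p = {}
    logs = []
    for key, members in sorted(targets.items()):
        vals = []
        for label in members:
            if label not in env.shifts:
                raise KeyError(f"no predicted shift for {label} in environment {env.env_id}")
            vals.append(env.shifts[label])
        d = index.get(members[0])
        if d is None:
            raise KeyError(f"no experimental distribution covers {members[0]}")
        p = shift_probability(float(np.mean(vals)), d)
        per_atom_p[key] = p
        logs.append(math.log(max(p, P_FLOOR)))
    pvalue = math.exp(sum(logs) / len(logs)) if logs else 1.0
    return EnvironmentScore(env_id=env.env_id, per_atom_p=per_atom_p, pvalue=pvalue)


def _rank_key(score):
    # higher p first; ties broken by env_id lexicographic order
    return (-score.pvalue, tuple(str(x) for x in score.env_id))


def rank_and_select(scores, n):
    """Sort scores by descending p-value and select the top-``n`` NMR set."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to rank")
    ordered = sorted(scores, key=_rank_key)
    k = min(n, len(ordered))
    ranked = [s.env_id for s in ordered]
    return EnsembleSelection(
        ranked=ranked,
        nmr_set=ranked[:k],
        md_set=[s.env_id for s in scores],
        n_selected=k,
        min_selected_pvalue=ordered[k - 1].pvalue,
        pvalues={s.env_id: s.pvalue for s in scores},
    )


class _HeapItem:
    """Wrapper ordering the top-N heap so its root is the worst kept score."""

    __slots__ = ("score", "key")

    def __init__(self, score):
        self.score = score
        # heap root = minimum = score that loses first: lowest p, and at
        # equal p the lexicographically largest env_id (ids earlier in
        # lexicographic order win ties).
        self.key = (score.pvalue, tuple(str(x) for x in score.env_id))

    def __lt__(self, other):
        if self.key[0] != other.key[0]:
            return self.key[0] < other.key[0]
        return self.key[1] > other.key[1]


def score_dataset(predictions, dists, atom_subset=None, n=5000, *,
                  average_equivalent=True, keep_per_atom=False):
    """Stream environments, score each, and select the top-``n`` NMR set.

    Single pass; memory is bounded by a top-``n`` heap plus per-
    environment summary rows.  Deterministic for a fixed input order
    (ties broken by env_id lexicographic order, independent of order).

    Returns
    -------
    (EnsembleSelection, pandas.DataFrame)
        The selection and a score table with one row per environment
        (columns run_id, frame, molecule, pvalue, selected, plus
        per-atom probabilities if ``keep_per_atom``).
    """
    dists = list(dists)
    heap = []
    seen = set()
    rows = []
    for env in predictions:
        if env.env_id in seen:
            raise ValueError(f"duplicate env_id {env.env_id}")
        seen.add(env.env_id)
        score = score_environment(env, dists, atom_subset,
                                  average_equivalent=average_equivalent)
        item = _HeapItem(score)
        if len(heap) < n:
            heapq.heappush(heap, item)
        elif heap[0] < item:  # item beats the current worst kept score
            heapq.heapreplace(heap, item)
        row = {
            "run_id": score.env_id[0],
            "frame": score.env_id[1],
            "molecule": score.env_id[2],
            "pvalue": score.pvalue,
        }
        if keep_per_atom:
            row.update({f"p_{k}": v for k, v in score.per_atom_p.items()})
        rows.append(row)
    if not rows:
        raise ValueError("empty prediction stream")

    kept = sorted((it.score for it in heap), key=_rank_key)
    table = pd.DataFrame(rows)
    selected_ids = [s.env_id for s in kept]
    selected_set = set(selected_ids)
    table["selected"] = [
        (r, f, m) in selected_set
        for r, f, m in zip(table.run_id, table.frame, table.molecule)
    ]
    md_set = list(seen)
    pvalues = dict(zip(zip(table.run_id, table.frame, table.molecule), table.pvalue))
    selection = EnsembleSelection(
        ranked=selected_ids,
        nmr_set=selected_ids,
        md_set=md_set,
        n_selected=len(selected_ids),
        min_selected_pvalue=kept[-1].pvalue,
        pvalues=pvalues,
    )
    return selection, table


# ---------------------------------------------------------------------------
# CSV dialects

def read_predictions(path_or_buf, referencing=None):
    """Yield EnvironmentShifts from a predictions CSV.

    Expected header: run_id,frame,molecule,atom_label,shift_ppm — or
    shielding_ppm, in which case ``referencing`` (a ShiftReferencing)
    must be given to convert shieldings to shifts.
    """
    from .spectra import nucleus_of, shielding_to_shift

    df = pd.read_csv(path_or_buf, comment="#")
    if "shift_ppm" not in df.columns:
        if "shielding_ppm" not in df.columns or referencing is None:
            raise ValueError(
                "predictions CSV needs a shift_ppm column, or shielding_ppm "
                "plus an explicit referencing"
            )
        df["shift_ppm"] = [
            shielding_to_shift(v, nucleus_of(lbl), referencing)
            for v, lbl in zip(df.shielding_ppm, df.atom_label)
        ]
    for (run, frame, mol), grp in df.groupby(["run_id", "frame", "molecule"], sort=False):
        yield EnvironmentShifts(
            env_id=(run, int(frame), int(mol)),
            shifts=dict(zip(grp.atom_label, grp.shift_ppm)),
        )


def write_scores(table, path, header_lines=()):
    """Write a score table CSV with optional provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)
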