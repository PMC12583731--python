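"""End-to-end pipeline: score -> select -> analyze -> energetics.

Chains the library stages over on-disk inputs and writes every stage
output (score table, selection, feature histograms with promotion
ratios, H-bond census, energy profiles) plus a run manifest with
input checksums, the seed and the package version, so a run is
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import (FileBackend, PairwiseBackend, extract_cluster,
                         formation_energy, sample_md_environments)
from .metrics import (FeatureSpec, HBondCriterion, hbond_census,
                      feature_values, make_feature_histogram, promotion_map)
from .scoring import read_predictions, score_dataset, write_scores
from .spectra import read_distributions
from .io import read_trajectory

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class ValidationError(ValueError):
    """Configuration or input validation failed (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    ``trajectories`` maps run_id -> extended-XYZ/PDB path;
    ``features`` is a list of dicts with keys kind, atoms (list of
    labels), and optionally scope, bin_width, range, periodic;
    ``donors`` lists [donor_h, donor_heavy] pairs for the H-bond
    census.
    """

    predictions: str
    distributions: str
    out_dir: str
    trajectories: dict = field(default_factory=dict)
    label_map: str | None = None
    atom_subset: list | None = None
    n_select: int = 5000
    features: list = field(default_factory=list)
    donors: list = field(default_factory=list)
    hbond: dict = field(default_factory=dict)
    acceptor_class_map: dict = field(default_factory=dict)
    energy_backend: str | None = None  # "toy" | "file" | None
    energies: str | None = None        # CSV for the file backend
    cluster_cutoff: float = 7.0
    md_sample_per_run: int = 1500
    seed: int = 0

    def validate(self):
        if self.n_select < 1:
            raise ValidationError("n_select must be >= 1")
        for path in [self.predictions, self.distributions,
                     *(self.trajectories or {}).values()]:
            if path and not os.path.exists(path):
                raise ValidationError(f"input path does not exist: {path}")
        if self.energy_backend == "file" and not self.energies:
            raise ValidationError("file energy backend needs an energies CSV")


def load_config(path):
    """Load a PipelineConfig from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig(**data)


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _feature_spec(fdict):
    return FeatureSpec(
        kind=fdict["kind"],
        atom_labels=tuple(fdict["atoms"]),
        scope=fdict.get("scope", "intra"),
        name=fdict.get("name", ""),
        donor_heavy=fdict.get("donor_heavy", ""),
    )


def _provenance(config, checksums):
    cfg_hash = hashlib.sha256(
        json.dumps(checksums, sort_keys=True).encode()
    ).hexdigest()[:16]
    return [
        f"shiftselect {__version__}",
        f"seed={config.seed}",
        f"config_hash={cfg_hash}",
    ] + [f"input {k} sha256={v}" for k, v in checksums.items()]


def run_pipeline(config: PipelineConfig):
    """Run score -> select -> analyze (-> energy) and write all outputs.

    Returns a report dict summarising each stage; every output CSV
    carries a provenance header and the manifest records input
    checksums, the seed and versions.  Idempotent for fixed inputs.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    checksums = {}
    for key, path in [("predictions", config.predictions),
                      ("distributions", config.distributions),
                      *[(f"trajectory:{r}", p) for r, p in (config.trajectories or {}).items()]]:
        if path:
            checksums[key] = _sha256(path)
    header = _provenance(config, checksums)
    report = {"stages": {}, "promoted_features": [], "no_promoted_features": None}

    # --- score and select ---------------------------------------------------
    try:
        dists = read_distributions(config.distributions)
        preds = read_predictions(config.predictions)
        selection, table = score_dataset(preds, dists, config.atom_subset,
                                         n=config.n_select)
    except Exception as err:
        raise StageError(f"scoring stage failed: {err}") from err
    write_scores(table, os.path.join(config.out_dir, "scores.csv"), header)
    sel_df = pd.DataFrame(
        [{"run_id": r, "frame": f, "molecule": m} for r, f, m in selection.nmr_set]
    )
    write_scores(sel_df, os.path.join(config.out_dir, "selection.csv"), header)
    report["stages"]["scoring"] = selection.summary()

    # --- structural analysis ------------------------------------------------
    environments = []
    frames_by_run = {}
    if config.trajectories:
        try:
            for run_id, path in sorted(config.trajectories.items()):
                frames = read_trajectory(path, config.label_map)
                frames_by_run[run_id] = [fr for _, fr in frames]
                for fidx, fr in enumerate(frames_by_run[run_id]):
                    for mol in fr.molecules:
                        environments.append(((run_id, fidx, mol.index), fr, mol.index))
        except Exception as err:
            raise StageError(f"trajectory stage failed: {err}") from err

    nmr_ids = set(selection.nmr_set)
    nmr_envs = [e for e in environments if e[0] in nmr_ids]
    criterion = HBondCriterion(**config.hbond) if config.hbond else HBondCriterion()

    hist_rows = []
    for fdict in config.features:
        spec = _feature_spec(fdict)
        if spec.kind == "hbond_acceptor":
            continue  # handled by the census
        try:
            _, vals_md = feature_values(environments, spec)
            _, vals_nmr = feature_values(nmr_envs, spec)
        except Exception as err:
            raise StageError(f"feature {spec.name} failed: {err}") from err
        periodic = fdict.get("periodic", spec.kind == "dihedral")
        bw = fdict.get("bin_width", 10.0 if spec.kind == "dihedral" else 0.5)
        hist = make_feature_histogram(
            vals_md, vals_nmr, bw, periodic=periodic,
            range_=tuple(fdict["range"]) if fdict.get("range") else None,
            name=spec.name,
        )
        promoted = [i for i, lbl in enumerate(hist.classification) if lbl == "promoted"]
        if promoted:
            report["promoted_features"].append(spec.name)
        for left, right, ratio, label in promotion_map(hist):
            i = int(np.searchsorted(hist.bin_edges, left))
            hist_rows.append({
                "feature": spec.name, "bin_left": left, "bin_right": right,
                "density_md": hist.density_md[i], "density_nmr": hist.density_nmr[i],
                "promotion": ratio, "class": label,
            })
    if hist_rows:
        write_scores(pd.DataFrame(hist_rows),
                     os.path.join(config.out_dir, "histograms.csv"), header)

    if config.donors and environments:
        census = hbond_census(environments, nmr_envs,
                              [tuple(d) for d in config.donors], criterion,
                              config.acceptor_class_map or None)
        rows = []
        for donor, classes in census.fractions.items():
            for cls, (fmd, fnmr) in classes.items():
                rows.append({"donor": donor, "acceptor_class": cls,
                             "fraction_md": fmd, "fraction_nmr": fnmr})
        write_scores(pd.DataFrame(rows),
                     os.path.join(config.out_dir, "hbond_census.csv"), header)
        report["stages"]["hbond_census"] = {d: len(c) for d, c in census.fractions.items()}

    # --- energetics ---------------------------------------------------------
    if config.energy_backend and environments:
        try:
            run_envs = {}
            for env_id, _, _ in environments:
                run_envs.setdefault(env_id[0], []).append(env_id)
            per_run = min(config.md_sample_per_run,
                          min(len(v) for v in run_envs.values()))
            md_sample = set(sample_md_environments(
                {r: v for r, v in run_envs.items()}, per_run, seed=config.seed))
            wanted = md_sample | nmr_ids
            frame_of = {e[0]: (e[1], e[2]) for e in environments}
            if config.energy_backend == "toy":
                backend = PairwiseBackend()
                energies = {}
                for env_id in sorted(wanted, key=str):
                    fr, midx = frame_of[env_id]
                    cl = extract_cluster(fr, midx, config.cluster_cutoff, env_id)
                    energies[env_id] = formation_energy(cl, backend).delta
            else:
                fb = FileBackend(config.energies)
                energies = {e: fb.energies_for(e).delta for e in sorted(wanted, key=str)
                            if e in fb._table}
            erows = [{"run_id": e[0], "frame": e[1], "molecule": e[2],
                      "delta_kjmol": d, "in_nmr_set": e in nmr_ids,
                      "in_md_sample": e in md_sample}
                     for e, d in energies.items()]
            write_scores(pd.DataFrame(erows),
                         os.path.join(config.out_dir, "energies.csv"), header)
            report["stages"]["energetics"] = {"n_clusters": len(energies)}
        except StageError:
            raise
        except Exception as err:
            raise StageError(f"energetics stage failed: {err}") from err

    report["no_promoted_features"] = not report["promoted_features"]
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": checksums,
        "n_select": config.n_select,
        "outputs": sorted(os.listdir(config.out_dir)),
        "report": report["stages"],
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return report
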