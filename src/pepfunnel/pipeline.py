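"""End-to-end orchestration of the design funnel on synthetic demo data.

``run_pipeline`` chains curation (interolog filtering of homolog triplets),
alignment refinement, generative-model training, library design and the
screening analytics, writing every stage artifact plus a manifest that
records the configuration, the per-stage random seeds (all derived from one
root seed) and a SHA-256 hash of each artifact, so a rerun with the same
configuration reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .alignment import sequence_weights, write_alignment
from .interolog import filter_triplets, triplet_consistency
from .library import build_library
from .pssm import PSSM
from .refine import refine_alignment
from .rbm import SequenceRBM
from .screen import fit_ic50, normalize_chip

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Demonstration-scale configuration; stage parameters default to the
    study values where they are stage parameters (16 columns, Z cutoff -0.3,
    5 chip repeats), with reduced model and sample sizes for desk-scale runs."""
    return {
        "seed": 0,
        "stages": ["curate", "refine", "train", "design", "screen"],
        "mfa": {
            "n_records": 400,
            "n_columns": 16,
            "n_genes": 4,
            "outlier_fraction": 0.08,
            "coupling_pairs": [[2, 12]],
            "coupling_strength": 0.6,
        },
        "refine": {"cutoff_z": -0.3, "n_updates": 600, "mc_steps": 5},
        "rbm": {
            "n_hidden": 8,
            "weight_l12": 0.1,
            "n_updates": 800,
            "mc_steps": 5,
            "n_chains": 50,
        },
        "ais": {"n_betas": 1000, "n_repeats": 5},
        "library": {
            "counts": {"crbm": 40, "crbm_lowT": 40, "pssm": 15, "random": 10, "natural": 15},
            "n_pool": 400,
            "beta_low_t": 2.0,
        },
        "chip": {"n_rows": 16, "n_cols": 16, "n_repeats": 5, "n_hits": 6},
        "fp": {"true_ic50s": [1.17, 10.2, 54.0]},
    }


def _sha256(path: Path) -> str:
    if path.suffix == ".npz":
        # hash array contents: the zip container embeds timestamps
        data = np.load(path)
        digest = hashlib.sha256()
        for key in sorted(data.files):
            digest.update(key.encode())
            digest.update(np.ascontiguousarray(data[key]).tobytes())
        return digest.hexdigest()
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(root_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: dict | None = None, outdir="pepfunnel_run") -> dict:
    """Execute the funnel stages listed in the configuration; returns the
    manifest (also written to ``manifest.json`` in the run directory)."""
    cfg = default_config()
    if config:
        for key, value in config.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg, "stages": {}, "artifacts": {}}
    root_seed = int(cfg["seed"])
    artifacts: dict[str, Path] = {}
    mfa = None
    rbm = None
    pssm = None

    if "curate" in cfg["stages"]:
        seed = _stage_seed(root_seed, "curate")
        triplets, _ = synthetic.make_triplets(seed=seed)
        kept, scores = filter_triplets(triplets, triplet_consistency(triplets))
        scores.to_frame().to_csv(outdir / "triplet_scores.csv", index=False)
        artifacts["triplet_scores"] = outdir / "triplet_scores.csv"
        mfa, _ = synthetic.make_mfa(seed=seed, **cfg["mfa"])
        write_alignment(mfa, outdir / "mfa_raw.fasta")
        artifacts["mfa_raw"] = outdir / "mfa_raw.fasta"
        manifest["stages"]["curate"] = {
            "seed": seed,
            "n_candidates_kept": len(kept.candidates),
            "n_raw_records": mfa.n_records,
        }

    if "refine" in cfg["stages"]:
        if mfa is None:
            raise RuntimeError("refine stage requires the curate stage")
        seed = _stage_seed(root_seed, "refine")
        mfa, report = refine_alignment(mfa, seed=seed, **cfg["refine"])
        write_alignment(mfa, outdir / "mfa_refined.fasta")
        report.to_frame().to_csv(outdir / "refinement_report.csv", index=False)
        artifacts["mfa_refined"] = outdir / "mfa_refined.fasta"
        artifacts["refinement_report"] = outdir / "refinement_report.csv"
        manifest["stages"]["refine"] = {
            "seed": seed,
            "n_kept": int(report.kept.sum()),
            "n_discarded": int((~report.kept).sum()),
        }

    if "train" in cfg["stages"]:
        if mfa is None:
            raise RuntimeError("train stage requires an alignment")
        seed = _stage_seed(root_seed, "train")
        weights = sequence_weights(mfa)
        pssm = PSSM(pseudocount=1.0).fit(mfa, sample_weight=weights)
        pssm.save(outdir / "pssm.txt")
        rbm = SequenceRBM(random_state=seed, **cfg["rbm"]).fit(mfa, sample_weight=weights)
        rbm.estimate_log_partition(random_state=seed, **cfg["ais"])
        rbm.save(outdir / "rbm.npz")
        artifacts["pssm"] = outdir / "pssm.txt"
        artifacts["rbm"] = outdir / "rbm.npz"
        manifest["stages"]["train"] = {
            "seed": seed,
            "log_partition": rbm.log_partition_,
            "log_partition_se": rbm.log_partition_se_,
            "mean_participation": float(rbm.participation_fractions().mean()),
        }

    if "design" in cfg["stages"]:
        if rbm is None or pssm is None:
            raise RuntimeError("design stage requires the train stage")
        seed = _stage_seed(root_seed, "design")
        library = build_library(rbm, pssm, mfa, seed=seed, **cfg["library"])
        library.to_csv(outdir / "library.csv", index=False)
        with open(outdir / "library.fasta", "w") as fh:
            for k, row in library.iterrows():
                fh.write(f">lib{k:04d}|source={row['source']}\n{row['sequence']}\n")
        artifacts["library_csv"] = outdir / "library.csv"
        artifacts["library_fasta"] = outdir / "library.fasta"
        manifest["stages"]["design"] = {
            "seed": seed,
            "panel_size": int(len(library)),
            "sources": library["source"].value_counts().to_dict(),
        }

    if "screen" in cfg["stages"]:
        seed = _stage_seed(root_seed, "screen")
        scan, truth = synthetic.make_chip(seed=seed, **cfg["chip"])
        zscores = normalize_chip(scan)
        zscores.to_csv(outdir / "chip_zscores.csv", index=False)
        artifacts["chip_zscores"] = outdir / "chip_zscores.csv"
        fp = synthetic.make_fp(seed=seed, **cfg["fp"])
        fits = []
        for pep, sub in fp.groupby("peptide"):
            fit = fit_ic50(sub["concentration_uM"].to_numpy(), sub["polarization"].to_numpy())
            fits.append(
                {
                    "peptide": pep,
                    "ic50_uM": fit.ic50,
                    "no_binding": fit.no_binding,
                    "true_ic50": float(sub["true_ic50"].iloc[0]),
                }
            )
        pd.DataFrame(fits).to_csv(outdir / "fp_fits.csv", index=False)
        artifacts["fp_fits"] = outdir / "fp_fits.csv"
        manifest["stages"]["screen"] = {
            "seed": seed,
            "n_hit_candidates": int((zscores.loc[~zscores["border"], "z"] > 3).sum()),
        }

    for name, path in artifacts.items():
        manifest["artifacts"][name] = {"path": path.name, "sha256": _sha256(path)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
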