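"""Configuration, fixture panels and artifact IO.

Config keys mirror the published parameter symbols (kg, fdie, cellVol, K, nG,
nGS, nGSt, g1, g2, nL, hlaL, hlaL0, kin, fout, CTL_ss, TCR_other, T_d, mu,
T_a, k_kill, k_mag, lam, phat1, phat2, alpha, beta, epsilon) so a YAML file
can be audited against the source table line by line. Unknown keys are
rejected with a nearest-match suggestion.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import fields, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .features import Neoantigen, elispot_to_immunogenicity
from .params import (ImmuneParams, Preset, TeslaCriteria, TeslaFeatureParams,
                     TumorParams)

__all__ = [
    "generate_fixture",
    "panel_to_neoantigens",
    "read_panel",
    "write_panel",
    "load_config",
    "apply_config",
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "write_cohort",
    "read_cohort",
]

PANEL_COLUMNS = ("id", "mhc_allele")  # plus R or elispot_score


def generate_fixture(kind: str, seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic neoantigen panel.

    'bbn963': 34 neoantigens on 2 alleles with nonnegative ELISpot-like
    scores — most zero or near zero, a handful strongly positive, matching
    the observation that generally fewer than 4 candidates are bona fide
    immunogenic. 'mc38': 489 neoantigens with R resampled from the scaled
    bbn963-like empirical distribution. Deterministic per (kind, seed).
    """
    rng = np.random.default_rng(seed)
    if kind == "bbn963":
        n = 34
        scores = np.zeros(n)
        n_hot = 3
        hot = rng.choice(n, size=n_hot, replace=False)
        scores[hot] = rng.uniform(50.0, 200.0, size=n_hot)
        warm = rng.random(n) < 0.3
        warm &= scores == 0
        scores[warm] = rng.exponential(5.0, size=int(warm.sum()))
        return pd.DataFrame({
            "id": np.arange(n),
            "elispot_score": scores,
            "mhc_allele": rng.integers(0, 2, size=n),
        })
    if kind == "mc38":
        base = generate_fixture("bbn963", seed=seed)
        R_pool = elispot_to_immunogenicity(base["elispot_score"].to_numpy())
        n = 489
        return pd.DataFrame({
            "id": np.arange(n),
            "R": rng.choice(R_pool, size=n, replace=True),
            "mhc_allele": rng.integers(0, 2, size=n),
        })
    raise ValueError("kind must be 'bbn963' or 'mc38'")


def panel_to_neoantigens(panel: pd.DataFrame) -> list[Neoantigen]:
    """Convert a tabular panel (R or elispot_score column) to Neoantigens."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if "R" in panel.columns:
        R = panel["R"].to_numpy(dtype=float)
    elif "elispot_score" in panel.columns:
        R = elispot_to_immunogenicity(panel["elispot_score"].to_numpy())
    else:
        raise ValueError("panel needs an 'R' or 'elispot_score' column")
    feature_cols = [c for c in ("affinity_nM", "stability_h", "agretopicity",
                                "tpm", "foreignness") if c in panel.columns]
    out = []
    for i, (_, row) in enumerate(panel.iterrows()):
        feats = ({c: float(row[c]) for c in feature_cols}
                 if feature_cols else None)
        out.append(Neoantigen(id=i, R=float(R[i]),
                              mhc_allele=int(row["mhc_allele"]),
                              features=feats))
    return out


def read_panel(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} missing columns: {missing}")
    return df


def write_panel(panel: pd.DataFrame, path: Union[str, Path]) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    panel.to_csv(path, sep=sep, index=False)


# -- config ------------------------------------------------------------------

_BLOCKS = {
    "tumor": TumorParams,
    "immune": ImmuneParams,
    "features": TeslaFeatureParams,
    "criteria": TeslaCriteria,
}


def _known_keys() -> dict[str, str]:
    keys = {}
    for block, cls in _BLOCKS.items():
        for f in fields(cls):
            keys[f.name] = block
    return keys


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML override map keyed by published parameter symbols."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of parameter overrides")
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    known = _known_keys()
    for key in cfg:
        if key in ("preset", "seed"):
            continue
        if key not in known:
            folded = {k.casefold(): k for k in known}
            hint = ([folded[key.casefold()]] if key.casefold() in folded
                    else difflib.get_close_matches(key, known, n=1,
                                                   cutoff=0.5))
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suffix}")


def apply_config(preset: Preset, cfg: dict) -> Preset:
    """Return a preset with config overrides applied (flat symbol names)."""
    validate_config(cfg)
    known = _known_keys()
    updates: dict[str, dict] = {}
    for key, value in cfg.items():
        if key in ("preset", "seed"):
            continue
        updates.setdefault(known[key], {})[key] = value
    out = preset
    for block, kv in updates.items():
        out = replace(out, **{block: replace(getattr(out, block), **kv)})
    return out


def write_resolved_config(preset: Preset, seed, path: Union[str, Path]) -> None:
    """Serialize the fully resolved parameter set beside run outputs.

    The document carries the seed, package version and a content hash of the
    resolved parameters, which together reproduce the run bit-identically.
    """
    import hashlib

    from . import __version__

    def block_dict(block):
        d = {}
        for f in fields(block):
            v = getattr(block, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif hasattr(v, "__dict__") and not isinstance(v, (int, float, str)):
                v = vars(v)
            d[f.name] = v
        return d

    doc = {
        "preset": preset.name,
        "seed": seed,
        "species": preset.species,
        "immunodeficient": preset.immunodeficient,
        "events_enabled": preset.events_enabled,
        "tumor": block_dict(preset.tumor),
        "immune": block_dict(preset.immune),
        "features": block_dict(preset.features),
        "criteria": block_dict(preset.criteria),
    }
    doc["version"] = __version__
    doc["content_sha1"] = hashlib.sha1(
        json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- artifacts ---------------------------------------------------------------

def write_trajectory(traj: pd.DataFrame, path: Union[str, Path]) -> None:
    traj.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"empty trajectory artifact: {path}")
    return df


def write_events(event_log, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for ev in event_log:
            fh.write(json.dumps({
                "day": ev.day, "type": ev.type, "parent_id": ev.parent_id,
                "child_id": ev.child_id, "target": ev.target}) + "\n")


def write_cohort(result, outdir: Union[str, Path]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(outdir / "cohort.csv", index=False,
                        float_format="%.17g")
    meta = {"preset": result.preset_name, "master_seed": result.master_seed,
            "n_tumors": len(result.table)}
    (outdir / "cohort_meta.json").write_text(json.dumps(meta, indent=2))
    for i, traj in enumerate(result.trajectories):
        write_trajectory(traj, outdir / f"treatment_{i:03d}.csv")


def read_cohort(outdir: Union[str, Path]):
    from .simulate import CohortResult

    outdir = Path(outdir)
    table = pd.read_csv(outdir / "cohort.csv")
    meta = json.loads((outdir / "cohort_meta.json").read_text())
    trajs = [read_trajectory(p)
             for p in sorted(outdir.glob("treatment_*.csv"))]
    return CohortResult(meta["preset"], meta["master_seed"], table, trajs)
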