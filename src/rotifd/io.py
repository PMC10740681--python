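"""Canonical CSV readers/writers (UTF-8, comma, header row, '.' decimal)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import CommunityMatrix
from .functional_traits import validate_trait_table
from .synthetic_community import SyntheticDataset

ENV_COLUMNS = [
    "sample_id", "site", "month",
    "chla", "tp", "tn", "sd", "cod",
    "temp", "dep", "do", "ph",
]


def read_community(path) -> CommunityMatrix:
    return CommunityMatrix.from_frame(pd.read_csv(path))


def write_community(community: CommunityMatrix, path) -> None:
    community.to_frame().to_csv(path, index=False)


def read_traits(path, vocabulary=None) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if vocabulary is None:
        return frame.set_index("taxon")
    return validate_trait_table(frame, vocabulary)


def write_traits(traits: pd.DataFrame, path) -> None:
    out = traits.reset_index() if traits.index.name == "taxon" else traits
    out.to_csv(path, index=False)


def read_environment(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_environment(env: pd.DataFrame, path) -> None:
    cols = [c for c in ENV_COLUMNS if c in env.columns]
    env[cols].to_csv(path, index=False)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the three canonical CSVs plus truth tables and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.csv",
        "traits": outdir / "traits.csv",
        "environment": outdir / "environment.csv",
        "truth": outdir / "truth.csv",
        "truth_samples": outdir / "truth_samples.csv",
        "config": outdir / "config.json",
    }
    write_community(dataset.community, paths["abundance"])
    write_traits(dataset.traits, paths["traits"])
    write_environment(dataset.environment, paths["environment"])
    dataset.truth_species[["taxon", "optimum", "tolerance"]].to_csv(
        paths["truth"], index=False
    )
    dataset.truth_samples.to_csv(paths["truth_samples"], index=False)
    paths["config"].write_text(dataset.config.to_json() + "\n", encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
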