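"""On-disk layout for cohort bundles (TSV + JSON/YAML, human-diffable)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import SimulationConfig
from .simulate import CohortBundle

FILES = {
    "participants": "participants.tsv",
    "metabolites": "metabolites.tsv",
    "registry": "registry.tsv",
    "traits": "traits.tsv",
}


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> list[Path]:
    """Write a bundle to ``out_dir``; returns the list of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, name in FILES.items():
        table: pd.DataFrame = getattr(bundle, attr)
        path = out / name
        index = attr != "registry"
        table.to_csv(path, sep="\t", index=index, na_rep="")
        written.append(path)
    if bundle.ground_truth is not None:
        path = out / "ground_truth.json"
        path.write_text(json.dumps(bundle.ground_truth, indent=2, sort_keys=True))
        written.append(path)
        if "config" in bundle.ground_truth:
            cfg = SimulationConfig.from_dict(bundle.ground_truth["config"])
            path = out / "config.yaml"
            path.write_text(cfg.to_yaml())
            written.append(path)
    return written


def read_cohort(in_dir: str | Path) -> CohortBundle:
    src = Path(in_dir)
    participants = pd.read_csv(src / FILES["participants"], sep="\t", index_col="participant_id")
    metabolites = pd.read_csv(src / FILES["metabolites"], sep="\t", index_col="participant_id")
    registry = pd.read_csv(src / FILES["registry"], sep="\t")
    traits = pd.read_csv(src / FILES["traits"], sep="\t", index_col="participant_id")
    if participants.index.duplicated().any():
        dup = participants.index[participants.index.duplicated()][0]
        raise ValueError(f"duplicate participant id in input: {dup!r}")
    ground_truth = None
    gt_path = src / "ground_truth.json"
    if gt_path.exists():
        ground_truth = json.loads(gt_path.read_text())
    return CohortBundle(
        participants=participants,
        metabolites=metabolites,
        registry=registry,
        traits=traits,
        ground_truth=ground_truth,
    )
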