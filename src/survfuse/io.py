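"""On-disk interchange: one CSV per modality, an outcome CSV (time, event) and
a YAML manifest assigning columns to blocks and declaring kinds/roles."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ModalityBlock, MultiModalDataset, SurvivalOutcome

__all__ = ["write_dataset", "read_dataset", "curves_to_frame", "coefficients_to_frame"]


def curves_to_frame(curves, sample_ids=None) -> pd.DataFrame:
    """Wide export of a SurvivalCurveSet: one row per sample, one column per
    grid time."""
    idx = sample_ids if sample_ids is not None else range(curves.n)
    return pd.DataFrame(curves.surv, index=idx,
                        columns=[f"t={t:g}" for t in curves.grid])


def coefficients_to_frame(block_betas: dict, feature_names: dict) -> pd.DataFrame:
    """Long export of per-block coefficients: (block, feature, value)."""
    rows = [
        {"block": blk, "feature": name, "value": float(v)}
        for blk, beta in block_betas.items()
        for name, v in zip(feature_names[blk], beta)
    ]
    return pd.DataFrame(rows)


def write_dataset(data: MultiModalDataset, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"blocks": [], "outcome": "outcome.csv"}
    for block in data.blocks:
        fname = f"{block.name}.csv"
        block.frame.to_csv(directory / fname, index=False)
        manifest["blocks"].append(
            {
                "name": block.name,
                "file": fname,
                "kinds": list(block.kinds),
                "role_tag": block.role_tag,
                "expression_like": bool(block.expression_like),
            }
        )
    pd.DataFrame(
        {
            "sample_id": data.sample_ids,
            "time": data.outcome.time,
            "event": data.outcome.event.astype(int),
        }
    ).to_csv(directory / "outcome.csv", index=False)
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_dataset(directory) -> MultiModalDataset:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    out = pd.read_csv(directory / manifest["outcome"])
    outcome = SurvivalOutcome(out["time"].to_numpy(), out["event"].to_numpy())
    blocks = []
    for spec in manifest["blocks"]:
        frame = pd.read_csv(directory / spec["file"])
        blocks.append(
            ModalityBlock(
                spec["name"], frame, list(spec["kinds"]), spec["role_tag"],
                bool(spec.get("expression_like", False)),
            )
        )
    return MultiModalDataset(blocks, outcome, np.asarray(out["sample_id"]))
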