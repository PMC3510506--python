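"""Readers, writers, configuration and run manifests.

TSV dialect: tab-separated, '#'-prefixed comment/header lines, '.' decimal,
no quoting; gene and sample identifiers are opaque strings.  The formats:

* expression TSV — genes x samples, first column ``gene``, then one column
  per sample id;
* annotation TSV — ``sample_id<TAB>stage``, sample order matching the
  expression columns, stage order = order of first appearance;
* time-course TSV — first column ``time``, then one column per gene, plus
  the same sidecar annotation mapping timepoint ids to stages;
* edge-list TSV — ``stage<TAB>regulator<TAB>target<TAB>strength``;
* network TSV — ``stage<TAB>regulator<TAB>target<TAB>coefficient<TAB>confidence``;
* SIF — ``regulator<TAB>activates|inhibits<TAB>target`` per stage, for
  Cytoscape import.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baselines import BaselineConfig
from .core import DCMConfig, FractionConfig, InferredStageNetworks
from .simulate import KineticNetwork, StagedExpressionData, TimeCourse
from .trends import TrendAssignment

__all__ = [
    "RunManifest",
    "read_expression",
    "write_expression",
    "read_timecourse",
    "write_timecourse",
    "read_edge_list",
    "write_edge_list",
    "write_networks",
    "read_networks",
    "write_sif",
    "write_trends",
    "load_config",
    "save_config",
]


@dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    seed: int
    config: dict
    inputs: dict[str, str]
    outputs: dict[str, str]
    stage_labels: list[str] = field(default_factory=list)
    started_at: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

def write_expression(data: StagedExpressionData, matrix_path, annotation_path) -> None:
    sample_ids, stages = [], []
    for lab, m in zip(data.stage_labels, data.matrices):
        for k in range(m.shape[1]):
            sample_ids.append(f"{lab}_{k + 1:03d}")
            stages.append(lab)
    df = pd.DataFrame(
        np.concatenate(data.matrices, axis=1), index=data.gene_ids, columns=sample_ids
    )
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample_id": sample_ids, "stage": stages}).to_csv(
        annotation_path, sep="\t", index=False
    )


def read_expression(matrix_path, annotation_path) -> StagedExpressionData:
    df = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    ann = _read_tsv(annotation_path)
    if set(ann.columns) != {"sample_id", "stage"}:
        raise ValueError("annotation must have columns sample_id and stage")
    missing = [s for s in ann["sample_id"] if s not in df.columns]
    extra = [s for s in df.columns if s not in set(ann["sample_id"])]
    if missing or extra:
        raise ValueError(
            f"stage mismatch between matrix and annotation: unannotated samples "
            f"{extra[:5]}, missing samples {missing[:5]}"
        )
    stage_order = list(dict.fromkeys(ann["stage"]))
    matrices = []
    for lab in stage_order:
        cols = ann.loc[ann["stage"] == lab, "sample_id"].tolist()
        matrices.append(df[cols].to_numpy(dtype=float))
    return StagedExpressionData(list(df.index.astype(str)), stage_order, matrices)


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------

def write_timecourse(tc: TimeCourse, matrix_path, annotation_path) -> None:
    df = pd.DataFrame(tc.values.T, columns=tc.gene_ids)
    df.insert(0, "time", tc.times)
    df.to_csv(matrix_path, sep="\t", index=False)
    ids = [f"t{k:04d}" for k in range(tc.times.size)]
    pd.DataFrame(
        {"sample_id": ids, "stage": [tc.stage_labels[s] for s in tc.stage_of_timepoint]}
    ).to_csv(annotation_path, sep="\t", index=False)


def read_timecourse(matrix_path, annotation_path) -> TimeCourse:
    df = pd.read_csv(matrix_path, sep="\t", comment="#")
    if df.columns[0] != "time":
        raise ValueError("time-course file must have a leading 'time' column")
    ann = _read_tsv(annotation_path)
    stage_order = list(dict.fromkeys(ann["stage"]))
    stage_idx = np.array([stage_order.index(s) for s in ann["stage"]])
    return TimeCourse(
        gene_ids=[str(c) for c in df.columns[1:]],
        stage_labels=stage_order,
        times=df["time"].to_numpy(dtype=float),
        values=df.iloc[:, 1:].to_numpy(dtype=float).T,
        stage_of_timepoint=stage_idx,
    )


# ---------------------------------------------------------------------------
# Edge lists, networks, SIF
# ---------------------------------------------------------------------------

def write_edge_list(net: KineticNetwork, path) -> None:
    rows = []
    for s, spec in enumerate(net.stages):
        b = net.strengths[s]
        for reg, tgt in sorted(net.true_edges(s)):
            rows.append((spec.label, net.gene_ids[reg], net.gene_ids[tgt], b[tgt, reg]))
    pd.DataFrame(rows, columns=["stage", "regulator", "target", "strength"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"stage", "regulator", "target"}
    if not required <= set(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    return df


def write_networks(nets: InferredStageNetworks, path) -> None:
    rows = []
    p = len(nets.gene_ids)
    for s, lab in enumerate(nets.stage_labels):
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                rows.append(
                    (
                        lab,
                        nets.gene_ids[j],
                        nets.gene_ids[i],
                        nets.coefficients[s, i, j],
                        nets.confidence[s, i, j],
                    )
                )
    pd.DataFrame(
        rows, columns=["stage", "regulator", "target", "coefficient", "confidence"]
    ).to_csv(path, sep="\t", index=False)


def read_networks(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"stage", "regulator", "target", "coefficient", "confidence"}
    if not required <= set(df.columns):
        raise ValueError(f"network file must have columns {sorted(required)}")
    return df


def write_sif(edges: dict[str, list[tuple[str, str, float, float]]], out_dir, prefix="network"):
    """One SIF file per stage: regulator<TAB>activates|inhibits<TAB>target."""
    out_dir = Path(out_dir)
    paths = []
    for lab, edge_list in edges.items():
        lines = [
            f"{reg}\t{'activates' if coef >= 0 else 'inhibits'}\t{tgt}"
            for reg, tgt, coef, _ in edge_list
        ]
        p = out_dir / f"{prefix}_{lab}.sif"
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(p)
    return paths


def write_trends(trends: TrendAssignment, path) -> None:
    rows = []
    for i, g in enumerate(trends.gene_ids):
        for s, lab in enumerate(trends.stage_labels):
            rows.append((g, lab, trends.direction_name(i, s), trends.discontinuity[i]))
    pd.DataFrame(rows, columns=["gene", "stage", "direction", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _plain(value):
    if isinstance(value, tuple):
        return list(value)
    return value


def _config_to_dict(dcm: DCMConfig, fc: FractionConfig) -> dict:
    d = {k: _plain(v) for k, v in dataclasses.asdict(dcm).items()}
    d["fractions"] = {k: _plain(v) for k, v in dataclasses.asdict(fc).items()}
    return d


def save_config(path, dcm: DCMConfig, fc: FractionConfig) -> None:
    path = Path(path)
    d = _config_to_dict(dcm, fc)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2, default=list) + "\n")


def load_config(path) -> tuple[DCMConfig, FractionConfig]:
    """Load a JSON or YAML config mirroring DCMConfig + FractionConfig."""
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    fd = d.pop("fractions", {})
    if "interpolation_fractions" in fd:
        fd["interpolation_fractions"] = tuple(fd["interpolation_fractions"])
    if d.get("penalty_grid") is not None:
        d["penalty_grid"] = tuple(d["penalty_grid"])
    return DCMConfig(**d), FractionConfig(**fd)
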