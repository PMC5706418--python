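"""Quantitative comparison of contact results and verification statistics.

Two probability-of-contact volumes are compared by the voxel-count-
normalized Euclidean distance

    d_ij = sqrt( sum_xyz (p_i - p_j)^2 / (X Y Z) ),

an L2 metric on [0, 1] probability volumes (so d_ij <= 1).

Expert verification labels (cells: good / correct / incorrect / missed;
contacts: excellent / acceptable / bad) are summarized by accuracy — the
fraction of items that at least one expert labeled positively — and
precision — the mean over expert pairs of the fraction of items on which
the two experts agree, after collapsing labels to a binary
positive/negative grouping.
"""

from __future__ import annotations

import json
import warnings
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .statistical import ProbabilityVolume

CELL_LABELS = ("good", "correct", "incorrect", "missed")
CONTACT_LABELS = ("excellent", "acceptable", "bad")

#: Default binary groupings: positive labels per label family.
CELL_POSITIVE = frozenset({"good", "correct"})
CONTACT_POSITIVE = frozenset({"excellent", "acceptable"})


def probability_distance(
    p_i: ProbabilityVolume | np.ndarray,
    p_j: ProbabilityVolume | np.ndarray,
    eight_bit_scale: bool = False,
) -> float:
    """Normalized Euclidean distance between two probability volumes.

    ``eight_bit_scale=True`` multiplies probabilities by 255 before the
    distance — a non-canonical convenience for comparing against tools that
    report the statistic on 8-bit-quantized maps.
    """
    a = p_i.values if isinstance(p_i, ProbabilityVolume) else np.asarray(p_i, dtype=float)
    b = p_j.values if isinstance(p_j, ProbabilityVolume) else np.asarray(p_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("probability grids are not congruent")
    scale = 255.0 if eight_bit_scale else 1.0
    diff = scale * (a - b)
    return float(np.sqrt((diff**2).sum() / a.size))


def distance_matrix(
    volumes: dict[str, ProbabilityVolume | np.ndarray]
) -> pd.DataFrame:
    """Symmetric pairwise distance table over named probability volumes."""
    names = list(volumes)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, j in combinations(names, 2):
        d = probability_distance(volumes[i], volumes[j])
        mat.loc[i, j] = mat.loc[j, i] = d
    return mat


def _as_table(table) -> pd.DataFrame:
    df = pd.DataFrame(table, columns=["item_id", "expert_id", "label"]) if not isinstance(
        table, pd.DataFrame
    ) else table
    required = {"item_id", "expert_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table needs columns {sorted(required)}")
    if df.duplicated(["item_id", "expert_id"]).any():
        raise ValueError("each (item, expert) may appear at most once")
    return df


def verification_accuracy(table, positive_labels=CONTACT_POSITIVE) -> float:
    """Fraction of items with at least one positive expert label."""
    df = _as_table(table)
    if df.empty:
        raise ValueError("label table is empty")
    per_item = df.groupby("item_id")["label"].apply(
        lambda labels: labels.isin(positive_labels).any()
    )
    return float(per_item.mean())


def verification_precision(table, positive_labels=CONTACT_POSITIVE) -> float:
    """Mean pairwise expert agreement after binary label grouping.

    For every pair of experts, the fraction of jointly labeled items on
    which both fall in the same group (positive vs negative); pairs with no
    overlapping items are excluded with a warning.
    """
    df = _as_table(table)
    experts = sorted(df["expert_id"].unique())
    if len(experts) < 2:
        raise ValueError("precision needs at least two experts")
    grouped = df.assign(positive=df["label"].isin(positive_labels)).pivot(
        index="item_id", columns="expert_id", values="positive"
    )
    ratios = []
    for e1, e2 in combinations(experts, 2):
        both = grouped[[e1, e2]].dropna()
        if both.empty:
            warnings.warn(f"experts {e1!r} and {e2!r} share no items; pair excluded")
            continue
        ratios.append(float((both[e1] == both[e2]).mean()))
    if not ratios:
        raise ValueError("no expert pair with overlapping items")
    return float(np.mean(ratios))


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read an (item_id, expert_id, label) CSV."""
    return _as_table(pd.read_csv(path))


def summarize_run(results_dir: str | Path) -> pd.DataFrame:
    """Aggregate per-pair JSON reports into one summary table.

    Each ``*.json`` report in ``results_dir`` is one row; malformed reports
    are skipped with a warning.  A final ``__aggregate__`` row carries the
    mean of the numeric columns.
    """
    results_dir = Path(results_dir)
    rows = []
    for report_path in sorted(results_dir.glob("*.json")):
        try:
            report = json.loads(report_path.read_text())
            if not isinstance(report, dict):
                raise ValueError("report is not an object")
        except (json.JSONDecodeError, ValueError) as err:
            warnings.warn(f"skipping malformed report {report_path.name}: {err}")
            continue
        rows.append({"pair": report_path.stem, **report})
    summary = pd.DataFrame(rows)
    if not summary.empty:
        numeric = summary.select_dtypes("number")
        aggregate = {"pair": "__aggregate__", **numeric.mean().to_dict()}
        summary = pd.concat([summary, pd.DataFrame([aggregate])], ignore_index=True)
    return summary
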