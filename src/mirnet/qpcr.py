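"""Relative quantification and differential calling for qPCR miRNA arrays.

A miRNome PCR array reports one threshold cycle (Ct) per miRNA per sample.
Abundance is normalized within each sample against a housekeeping small RNA
(e.g. SNOR73A for miRNA panels, HPRT for mRNA assays)::

    dCt(f, s) = Ct(f, s) - Ct(reference, s)
    q(f, s)   = 10000 / 2**dCt(f, s)

``q`` is a dimensionless relative quantity: one cycle of dCt corresponds to
a twofold change in abundance, and a feature as abundant as the reference
scores exactly 10,000.  Between-group fold changes are ratios of geometric
means of ``q`` (equivalently, 2 to the power of the difference of group-mean
dCt), and a feature is called differential when the fold-change magnitude
``max(FC, 1/FC)`` meets an inclusive threshold.

Undetected wells (Ct beyond the detection limit) carry NaN and are excluded
by a per-group detection rule rather than producing infinite fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QUANT_SCALE",
    "DEFAULT_DETECTION_LIMIT",
    "CtTable",
    "DeltaCtTable",
    "RelExprTable",
    "ComparisonProfile",
    "normalize_delta_ct",
    "relative_quantity",
    "group_fold_change",
    "call_differential",
    "common_detected_features",
]

#: Scaling constant of the relative-quantification transform 10000/2**dCt.
QUANT_SCALE = 10_000.0

#: Ct above this value is treated as undetected.
DEFAULT_DETECTION_LIMIT = 35.0

#: String used for undetected wells in CSV files (vendor convention).
UNDETECTED_TOKEN = "Undetermined"


class ReferenceUndetectedError(ValueError):
    """The housekeeping feature is missing or undetected in some sample."""


@dataclass(frozen=True)
class CtTable:
    """Ct matrix (features x samples) with group labels and a reference feature.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (case-sensitive strings), one column
        per sample id.  Undetected wells are NaN.
    groups
        Mapping sample id -> group name; every column must be mapped.
    reference
        Feature id of the housekeeping reference; must be present and
        detected in every sample.
    detection_limit
        Ct values above this are considered undetected.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    reference: str
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        if self.reference not in self.values.index:
            raise ReferenceUndetectedError(
                f"reference feature {self.reference!r} not on the panel"
            )
        ref = self.values.loc[self.reference]
        bad = ref.index[ref.isna() | (ref > self.detection_limit)].tolist()
        if bad:
            raise ReferenceUndetectedError(
                f"reference feature {self.reference!r} undetected in "
                f"sample(s): {bad}"
            )
        finite = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.nanmin(finite) <= 0 or np.nanmax(finite) > 45:
                raise ValueError("Ct values must lie in (0, 45] or be NaN")

    @property
    def features(self) -> list[str]:
        """Panel feature ids excluding the reference."""
        return [f for f in self.values.index if f != self.reference]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, group: str) -> list[str]:
        out = [s for s in self.values.columns if self.groups[s] == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected wells (finite Ct within the limit)."""
        return self.values.notna() & (self.values <= self.detection_limit)

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, ct_path: str | Path, groups_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "feature"
        out = out.astype(object).where(out.notna(), UNDETECTED_TOKEN)
        out.to_csv(ct_path)
        gm = pd.DataFrame(
            {"sample": list(self.values.columns),
             "group": [self.groups[s] for s in self.values.columns]}
        )
        gm.to_csv(groups_path, index=False)

    @classmethod
    def read_csv(
        cls,
        ct_path: str | Path,
        groups_path: str | Path,
        reference: str,
        detection_limit: float = DEFAULT_DETECTION_LIMIT,
    ) -> "CtTable":
        raw = pd.read_csv(ct_path, index_col=0)
        values = raw.replace(UNDETECTED_TOKEN, np.nan).astype(float)
        gm = pd.read_csv(groups_path)
        groups = dict(zip(gm["sample"].astype(str), gm["group"].astype(str)))
        return cls(values=values, groups=groups, reference=reference,
                   detection_limit=detection_limit)


@dataclass(frozen=True)
class DeltaCtTable:
    """Per-sample reference-normalized Ct values (dCt, cycles)."""

    values: pd.DataFrame
    groups: Mapping[str, str]
    reference: str

    def samples_of(self, group: str) -> list[str]:
        out = [s for s in self.values.columns if self.groups[s] == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out


@dataclass(frozen=True)
class RelExprTable:
    """Relative quantities q = 10000 / 2**dCt (dimensionless)."""

    values: pd.DataFrame
    groups: Mapping[str, str]
    reference: str


DIRECTIONS = ("up", "down", "unchanged", "undetected")


@dataclass(frozen=True)
class ComparisonProfile:
    """Up/down/unchanged/undetected partition of a panel for one comparison.

    ``table`` is indexed by feature id with columns ``magnitude`` (fold-change
    magnitude, max(FC, 1/FC); NaN when undetected) and ``direction``.
    """

    comparison_id: str
    numerator: str
    denominator: str
    table: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        bad = set(self.table["direction"]) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"invalid directions: {sorted(bad)}")

    def _members(self, direction: str) -> list[str]:
        return sorted(self.table.index[self.table["direction"] == direction])

    @property
    def up(self) -> list[str]:
        return self._members("up")

    @property
    def down(self) -> list[str]:
        return self._members("down")

    @property
    def called(self) -> list[str]:
        return sorted(set(self.up) | set(self.down))

    def direction_of(self, feature: str) -> str:
        return str(self.table.loc[feature, "direction"])

    def directions(self) -> dict[str, str]:
        """Direction attribute per called miRNA (up/down only)."""
        return {f: str(d) for f, d in self.table["direction"].items()
                if d in ("up", "down")}

    # -- I/O ---------------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(2, "threshold", self.threshold)
        out.index.name = "feature"
        out.to_csv(path, sep="\t")

    def to_dict(self) -> dict:
        return {
            "comparison_id": self.comparison_id,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "threshold": self.threshold,
            "up": self.up,
            "down": self.down,
            "n_up": len(self.up),
            "n_down": len(self.down),
        }

    @classmethod
    def from_calls(
        cls,
        comparison_id: str,
        numerator: str,
        denominator: str,
        up: list[str],
        down: list[str],
        threshold: float,
        magnitude: float | Mapping[str, float] = np.nan,
    ) -> "ComparisonProfile":
        """Build a profile from explicit up/down lists (worked examples)."""
        features = list(up) + list(down)
        if isinstance(magnitude, Mapping):
            mags = [float(magnitude[f]) for f in features]
        else:
            mags = [float(magnitude)] * len(features)
        table = pd.DataFrame(
            {"magnitude": mags,
             "direction": ["up"] * len(up) + ["down"] * len(down)},
            index=pd.Index(features, name="feature"),
        )
        return cls(comparison_id, numerator, denominator, table, threshold)


def normalize_delta_ct(ct: CtTable) -> DeltaCtTable:
    """Subtract the reference feature's Ct from every feature, per sample.

    Undetected wells propagate NaN.  The reference's own row is identically
    zero.  Raises :class:`ReferenceUndetectedError` (at table construction)
    if the reference is undetected anywhere.
    """
    ref = ct.values.loc[ct.reference]
    delta = ct.values.sub(ref, axis="columns")
    return DeltaCtTable(values=delta, groups=dict(ct.groups),
                        reference=ct.reference)


def relative_quantity(delta_ct):
    """Relative quantity ``10000 / 2**dCt`` for scalar or array dCt.

    NaN (undetected) inputs yield NaN, never a number.
    """
    return QUANT_SCALE / np.power(2.0, delta_ct)


def to_relative_expression(delta: DeltaCtTable) -> RelExprTable:
    """Apply the relative-quantification transform to a whole dCt table."""
    return RelExprTable(values=relative_quantity(delta.values),
                        groups=dict(delta.groups), reference=delta.reference)


def _group_mean_dct(
    delta: DeltaCtTable,
    detected: pd.DataFrame,
    group: str,
    min_detect_frac: float,
) -> tuple[pd.Series, pd.Series]:
    """Mean dCt over detected wells per feature, plus a usability mask.

    A feature is usable in a group when detected in >= ``min_detect_frac``
    of that group's replicates and in at least two wells.
    """
    samples = delta.samples_of(group)
    sub = delta.values[samples]
    det = detected[samples]
    n_det = det.sum(axis=1)
    usable = (n_det >= 2) & (n_det >= min_detect_frac * len(samples))
    mean = sub.where(det).mean(axis=1)
    return mean, usable


def group_fold_change(
    ct: CtTable,
    numerator: str,
    denominator: str,
    min_detect_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-feature fold change between two groups.

    FC is the ratio of geometric-mean relative quantities, computed on the
    dCt scale as ``2**(mean_dCt_denominator - mean_dCt_numerator)``; the two
    are algebraically identical because q is an exponential of dCt.

    Returns a DataFrame indexed by panel feature (reference excluded) with
    columns ``fc`` (signed ratio), ``magnitude`` (max(FC, 1/FC)) and
    ``detected`` (bool; False when either group fails the detection rule —
    such features carry NaN fc/magnitude).
    """
    for g in (numerator, denominator):
        ct.samples_of(g)  # raises KeyError on unknown group
    delta = normalize_delta_ct(ct)
    detected = ct.detected()
    mean_num, ok_num = _group_mean_dct(delta, detected, numerator,
                                       min_detect_frac)
    mean_den, ok_den = _group_mean_dct(delta, detected, denominator,
                                       min_detect_frac)
    fc = np.power(2.0, mean_den - mean_num)
    usable = ok_num & ok_den
    fc = fc.where(usable)
    out = pd.DataFrame({
        "fc": fc,
        "magnitude": np.maximum(fc, 1.0 / fc),
        "detected": usable,
    })
    return out.loc[ct.features]


def call_differential(
    fc_table: pd.DataFrame,
    threshold: float,
    comparison_id: str = "",
    numerator: str = "",
    denominator: str = "",
) -> ComparisonProfile:
    """Call features up/down at an inclusive fold-change-magnitude threshold.

    ``fc_table`` is the output of :func:`group_fold_change`.  A feature is
    called up when FC >= threshold, down when FC <= 1/threshold (i.e.
    reciprocal magnitude >= threshold); detected features below threshold
    are ``unchanged`` and detection-rule failures are ``undetected``.
    """
    if not threshold >= 1.0:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    fc = fc_table["fc"]
    detected = fc_table["detected"].astype(bool)
    direction = pd.Series("unchanged", index=fc_table.index, dtype=object)
    direction[~detected] = "undetected"
    direction[detected & (fc >= threshold)] = "up"
    direction[detected & (fc <= 1.0 / threshold)] = "down"
    table = pd.DataFrame({"magnitude": fc_table["magnitude"],
                          "direction": direction})
    return ComparisonProfile(
        comparison_id=comparison_id or f"{numerator}_vs_{denominator}",
        numerator=numerator,
        denominator=denominator,
        table=table,
        threshold=float(threshold),
    )


def common_detected_features(
    ct: CtTable,
    min_detect_frac: float = 0.5,
) -> list[str]:
    """Panel features detected (per the group detection rule) in every group.

    This is the "expressed in common" filter applied before profiling:
    a feature counts when it is detected in at least ``min_detect_frac`` of
    each group's replicates (and >= 2 wells per group).
    """
    detected = ct.detected()
    groups = sorted(set(ct.groups.values()))
    ok = pd.Series(True, index=ct.values.index)
    for g in groups:
        samples = ct.samples_of(g)
        n_det = detected[samples].sum(axis=1)
        ok &= (n_det >= 2) & (n_det >= min_detect_frac * len(samples))
    return [f for f in ct.features if ok[f]]
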