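"""Quality parameters, references and four-zone classification.

Every measured parameter (retention-time deviation, mass accuracy in ppm,
feature-area bias in percent) is compared against three ascending tolerance
limits ``(g, y, o)`` delimiting the four zones:

* green  — ``|value| ≤ g``
* yellow — ``g < |value| ≤ y``
* orange — ``y < |value| ≤ o``
* red    — ``|value| > o``

References are either fixed (taken from the target list: expected tR,
theoretical m/z) or data-based (the arithmetic mean of the found values
within a scope, per measurement sequence or global). Feature area has no
theoretical value, so its default reference is the per-sequence mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import SequenceEntry, TargetFeature

__all__ = [
    "ZONES",
    "ToleranceScheme",
    "FeatureResult",
    "ppm_error",
    "rt_deviation",
    "area_bias",
    "classify",
    "evaluate_results",
    "summarize",
]

ZONES = ("green", "yellow", "orange", "red", "missing")

Param = Literal["rt", "ppm", "area"]
ReferenceMode = Literal["fixed", "data_mean"]
ReferenceScope = Literal["per_sequence", "global"]


@dataclass(frozen=True)
class ToleranceScheme:
    """Four-zone limits and reference policy for the three QC parameters.

    Limits are per parameter ``(g, y, o)``: ppm for mass accuracy, seconds
    for retention-time deviation, percent for area bias. Defaults: mass
    accuracy (3, 5, 8) ppm; tR (6, 12, 30) s; area bias (20, 30, 50) %.
    """

    ppm_limits: Tuple[float, float, float] = (3.0, 5.0, 8.0)
    rt_limits_s: Tuple[float, float, float] = (6.0, 12.0, 30.0)
    area_limits_pct: Tuple[float, float, float] = (20.0, 30.0, 50.0)
    reference_mode: Dict[Param, ReferenceMode] = field(
        default_factory=lambda: {"rt": "fixed", "ppm": "fixed", "area": "data_mean"}
    )
    reference_scope: ReferenceScope = "per_sequence"

    def __post_init__(self) -> None:
        for name, lim in (
            ("ppm", self.ppm_limits),
            ("rt", self.rt_limits_s),
            ("area", self.area_limits_pct),
        ):
            g, y, o = lim
            if not (0 < g < y < o):
                raise ValueError(f"{name} limits must be ascending and positive, got {lim}")

    def limits(self, param: Param) -> Tuple[float, float, float]:
        return {"ppm": self.ppm_limits, "rt": self.rt_limits_s, "area": self.area_limits_pct}[param]


@dataclass
class FeatureResult:
    """All QC values for one (target feature, data file) pair."""

    feature: TargetFeature
    entry: SequenceEntry
    category: str
    found: bool
    rt_s: Optional[float] = None
    rt_dev_s: Optional[float] = None
    mz: Optional[float] = None
    ppm_error: Optional[float] = None
    area: Optional[float] = None
    area_bias_pct: Optional[float] = None
    ria: Optional[float] = None
    zones: Dict[str, str] = field(default_factory=dict)


def ppm_error(measured_mz: float, reference_mz: float) -> float:
    """Signed mass accuracy: ``(measured − reference) / reference × 1e6`` ppm."""
    if reference_mz <= 0:
        raise ValueError("reference m/z must be positive")
    return (measured_mz - reference_mz) / reference_mz * 1e6


def rt_deviation(measured_rt: float, reference_rt: float) -> float:
    """Signed retention-time deviation in seconds."""
    return measured_rt - reference_rt


def area_bias(area: float, reference_area: float) -> float:
    """Signed relative area bias in percent of the reference area."""
    if reference_area <= 0:
        raise ValueError("reference area must be positive")
    return (area - reference_area) / reference_area * 100.0


def classify(value: Optional[float], limits: Tuple[float, float, float]) -> str:
    """Map an absolute deviation onto a four-colour zone (limits inclusive)."""
    g, y, o = limits
    if not (g < y < o):
        raise ValueError("limits must be ascending")
    if value is None or not np.isfinite(value):
        return "missing"
    v = abs(value)
    if v <= g:
        return "green"
    if v <= y:
        return "yellow"
    if v <= o:
        return "orange"
    return "red"


def _scope_key(result: FeatureResult, scope: ReferenceScope) -> Tuple:
    if scope == "per_sequence":
        return (result.feature.name, result.feature.ion.label, result.entry.sequence_id)
    return (result.feature.name, result.feature.ion.label)


def evaluate_results(results: Sequence[FeatureResult], scheme: ToleranceScheme) -> List[FeatureResult]:
    """Fill deviations and zones on raw measurements, resolving references.

    ``rt`` and ``ppm`` use fixed references from the target list unless the
    scheme says ``data_mean``, in which case the reference is the mean of
    found values within the reference scope. ``area`` always needs a
    data-based reference under ``data_mean`` (the default); a scope where
    nothing was found leaves the area zone missing.
    """
    # data-based references per scope
    means: Dict[str, Dict[Tuple, float]] = {}
    for param, getter in (("rt", lambda r: r.rt_s), ("ppm", lambda r: r.mz), ("area", lambda r: r.area)):
        if scheme.reference_mode.get(param) != "data_mean":
            continue
        buckets: Dict[Tuple, List[float]] = {}
        for r in results:
            v = getter(r)
            if r.found and v is not None:
                buckets.setdefault(_scope_key(r, scheme.reference_scope), []).append(v)
        means[param] = {k: float(np.mean(v)) for k, v in buckets.items()}

    out: List[FeatureResult] = []
    for r in results:
        r = replace(r, zones=dict(r.zones))
        if not r.found:
            r.zones = {p: "missing" for p in ("rt", "ppm", "area")}
            out.append(r)
            continue
        key = _scope_key(r, scheme.reference_scope)
        # retention time
        if r.rt_s is not None:
            ref = means.get("rt", {}).get(key) if scheme.reference_mode.get("rt") == "data_mean" else r.feature.expected_rt_s
            if ref is not None:
                r.rt_dev_s = rt_deviation(r.rt_s, ref)
        r.zones["rt"] = classify(r.rt_dev_s, scheme.rt_limits_s)
        # mass accuracy
        if r.mz is not None:
            ref = means.get("ppm", {}).get(key) if scheme.reference_mode.get("ppm") == "data_mean" else r.feature.theoretical_mz
            if ref is not None:
                r.ppm_error = ppm_error(r.mz, ref)
        r.zones["ppm"] = classify(r.ppm_error, scheme.ppm_limits)
        # feature area
        if r.area is not None:
            if scheme.reference_mode.get("area") == "data_mean":
                ref = means.get("area", {}).get(key)
            else:
                ref = None  # no theoretical area exists
            if ref is not None and ref > 0:
                r.area_bias_pct = area_bias(r.area, ref)
        r.zones["area"] = classify(r.area_bias_pct, scheme.area_limits_pct)
        out.append(r)
    return out


_SUMMARY_PARAMS = {
    "tR_min": lambda r: r.rt_s / 60.0 if r.rt_s is not None else np.nan,
    "mz": lambda r: r.mz if r.mz is not None else np.nan,
    "ppm_error": lambda r: r.ppm_error if r.ppm_error is not None else np.nan,
    "area": lambda r: r.area if r.area is not None else np.nan,
    "ria": lambda r: r.ria if r.ria is not None else np.nan,
}


def summarize(results: Sequence[FeatureResult]) -> pd.DataFrame:
    """Per-feature summary statistics grouped by sequence and by sample category.

    For each group and parameter: n (found results), arithmetic mean, sample
    standard deviation (n−1) and relative standard deviation in percent.
    Not-found results are excluded from the statistics but counted in
    ``n_missing``.
    """
    rows = []
    for scope_name, keyfn in (
        ("sequence", lambda r: r.entry.sequence_id),
        ("category", lambda r: r.category),
    ):
        groups: Dict[Tuple, List[FeatureResult]] = {}
        for r in results:
            groups.setdefault((r.feature.name, r.feature.ion.label, keyfn(r)), []).append(r)
        for (feat, ion, grp), members in groups.items():
            found = [m for m in members if m.found]
            row = {
                "feature": feat,
                "ion": ion,
                "scope": scope_name,
                "group": grp,
                "n": len(found),
                "n_missing": len(members) - len(found),
            }
            for pname, getter in _SUMMARY_PARAMS.items():
                vals = np.asarray([getter(m) for m in found], dtype=float)
                vals = vals[np.isfinite(vals)]
                if len(vals) == 0:
                    mean = sd = rsd = np.nan
                else:
                    mean = float(np.mean(vals))
                    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                    rsd = sd / mean * 100.0 if mean != 0 else np.nan
                row[f"{pname}_mean"] = mean
                row[f"{pname}_sd"] = sd
                row[f"{pname}_rsd_pct"] = rsd
            rows.append(row)
    return pd.DataFrame(rows)
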