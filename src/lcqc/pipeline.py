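"""End-to-end screening: read runs, measure targets, classify, summarize."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .extraction import PeakPickingSettings, measure_feature
from .io_formats import (
    MzXMLError,
    SampleCategory,
    SequenceEntry,
    TargetFeature,
    categorize_samples,
    read_mzxml,
)
from .qc_metrics import FeatureResult, ToleranceScheme, evaluate_results, summarize

__all__ = ["ScreenParams", "ScreenOutcome", "screen"]

log = logging.getLogger(__name__)


@dataclass
class ScreenParams:
    """Processing parameters for a screening run.

    The EIC window default (±10 ppm) deliberately exceeds the outermost
    tolerance limit of the default zone scheme (±8 ppm red): a mass drift can
    only be measured and flagged if the extraction window still captures the
    drifted centroids.
    """

    ppm_window: float = 10.0
    rt_tol_s: float = 30.0
    separator: str = "_"
    compute_ria: bool = False
    keep_eics: bool = True  # retain EIC traces for the overlay plots
    scheme: ToleranceScheme = field(default_factory=ToleranceScheme)
    peak_settings: PeakPickingSettings = field(default_factory=PeakPickingSettings)


@dataclass
class ScreenOutcome:
    """Everything a screening run produced."""

    results: List[FeatureResult]
    stats: pd.DataFrame
    categories: List[SampleCategory]
    failed_files: List[Path]
    #: (feature name, ion label, sequence id, file name) -> (rt s, intensity)
    eics: Dict[tuple, tuple] = field(default_factory=dict)

    def zone_counts(self) -> Dict[str, int]:
        counts = {z: 0 for z in ("green", "yellow", "orange", "red", "missing")}
        for r in self.results:
            for z in r.zones.values():
                counts[z] += 1
        return counts


def screen(
    entries: Sequence[SequenceEntry],
    targets: Sequence[TargetFeature],
    params: Optional[ScreenParams] = None,
) -> ScreenOutcome:
    """Screen every target feature in every data file.

    A file that cannot be read is logged and reported as all-missing for
    every target; it never aborts the campaign.
    """
    params = params or ScreenParams()
    categories = categorize_samples(entries, params.separator)
    cat_of = {id(e): c.name for c in categories for e in c.members}
    results: List[FeatureResult] = []
    failed: List[Path] = []
    eics: Dict[tuple, tuple] = {}
    for entry in entries:
        run = None
        if not entry.missing:
            try:
                run = read_mzxml(entry.file_path)
            except MzXMLError as exc:
                log.warning("skipping unreadable file: %s", exc)
        if run is None:
            failed.append(entry.file_path)
        category = cat_of[id(entry)]
        for target in targets:
            if run is None:
                results.append(FeatureResult(feature=target, entry=entry, category=category, found=False))
                continue
            m = measure_feature(
                run,
                target,
                ppm=params.ppm_window,
                rt_tol=params.rt_tol_s,
                settings=params.peak_settings,
                compute_ria=params.compute_ria,
            )
            if m is None:
                results.append(FeatureResult(feature=target, entry=entry, category=category, found=False))
                continue
            if params.keep_eics:
                eics[(target.name, target.ion.label, entry.sequence_id, entry.file_path.name)] = (
                    m.eic.rt.copy(),
                    m.eic.intensity.copy(),
                )
            results.append(
                FeatureResult(
                    feature=target,
                    entry=entry,
                    category=category,
                    found=True,
                    rt_s=m.peak.apex_rt,
                    mz=m.measured_mz,
                    area=m.peak.area,
                    ria=m.measured_ria,
                )
            )
        log.info("processed %s", entry.file_path.name)
    results = evaluate_results(results, params.scheme)
    stats = summarize(results)
    return ScreenOutcome(
        results=results, stats=stats, categories=categories, failed_files=failed, eics=eics
    )
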