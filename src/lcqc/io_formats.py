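"""Sequence lists, target-feature tables, centroided mzXML and tabular output.

Conventions:

* Sequence CSVs need a ``file`` column; an optional ``sequence`` column labels
  the measurement sequence (default: one sequence per CSV, named after the
  CSV stem) and an optional ``acquisition_time`` column carries ISO-8601
  timestamps.
* Target tables (CSV or TSV by extension) need columns ``name``, ``formula``,
  ``target_mz``, ``ion``, ``expected_tR_min``, ``group``; either a formula or
  a target m/z must be given per row.
* Retention times are seconds internally and minutes in user-facing tables.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mzxml as _pyteomics_mzxml

from . import chem

__all__ = [
    "SequenceEntry",
    "SampleCategory",
    "CentroidRun",
    "TargetFeature",
    "FormatError",
    "MzXMLError",
    "read_sequence_csv",
    "categorize_samples",
    "read_mzxml",
    "read_targets",
    "write_results",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A tabular input does not follow the documented layout."""


class MzXMLError(IOError):
    """An mzXML file could not be decoded."""


@dataclass
class SequenceEntry:
    """One data file at its position in a measurement sequence."""

    file_path: Path
    sequence_id: str
    order_index: int  # 1-based within the sequence
    acquisition_time: Optional[datetime] = None
    missing: bool = False

    @property
    def stem(self) -> str:
        return self.file_path.stem


@dataclass
class SampleCategory:
    """A sample-type category (blank, standard QC, matrix QC, sample, ...)."""

    name: str
    members: List[SequenceEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CentroidRun:
    """One centroided mzXML file in memory (MS¹ scans only).

    ``rts`` holds per-scan retention times in seconds, strictly increasing;
    ``mzs[i]`` / ``intensities[i]`` are the ascending centroid m/z values and
    their intensities for scan ``i``.
    """

    rts: np.ndarray
    mzs: List[np.ndarray]
    intensities: List[np.ndarray]
    polarity: Optional[str] = None
    source_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if len(self.mzs) != len(self.rts) or len(self.intensities) != len(self.rts):
            raise ValueError("spectra arrays must be congruent with retention times")
        if len(self.rts) > 1 and not np.all(np.diff(self.rts) > 0):
            raise ValueError("retention times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(self.rts)


@dataclass
class TargetFeature:
    """One analyte × ion species to screen for.

    Exactly one of ``formula`` / ``target_mz`` is required; if both are given
    they must agree to 0.001 Da. ``expected_rt_s`` is in seconds.
    """

    name: str
    ion: chem.IonSpecies
    expected_rt_s: float
    formula: Optional[chem.Formula] = None
    target_mz: Optional[float] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.formula is None and self.target_mz is None:
            raise FormatError(f"target {self.name!r}: neither formula nor target m/z given")
        if self.expected_rt_s < 0:
            raise FormatError(f"target {self.name!r}: negative expected retention time")
        if self.formula is not None:
            computed = chem.adduct_mz(chem.monoisotopic_mass(self.formula), self.ion)
            if self.target_mz is not None and abs(computed - self.target_mz) > 0.001:
                raise FormatError(
                    f"target {self.name!r}: stated m/z {self.target_mz} deviates from "
                    f"{computed:.4f} computed from {self.formula.hill()} {self.ion.label} "
                    f"by more than 0.001 Da"
                )

    @property
    def theoretical_mz(self) -> float:
        if self.formula is not None:
            return chem.adduct_mz(chem.monoisotopic_mass(self.formula), self.ion)
        assert self.target_mz is not None
        return self.target_mz

    @property
    def theoretical_ria(self) -> Optional[float]:
        if self.formula is not None and self.formula["C"] >= 1:
            return chem.theoretical_ria(self.formula)
        return None


# ---------------------------------------------------------------------------
# sequence CSVs


def read_sequence_csv(
    path: Path | str,
    delimiter: str = ",",
    default_sequence: Optional[str] = None,
    check_exists: bool = True,
) -> List[SequenceEntry]:
    """Read one sequence CSV into :class:`SequenceEntry` objects in file order.

    Files are resolved relative to the CSV's directory. Rows keep their CSV
    order; ``order_index`` is assigned 1..n per sequence. A missing data file
    sets the entry's ``missing`` flag instead of failing.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    cols = [c.strip().lower() for c in table.columns]
    table.columns = cols
    if "file" not in cols:
        raise FormatError(
            f"{path}: sequence CSV needs a 'file' column; found columns {cols}"
        )
    seq_default = default_sequence if default_sequence is not None else path.stem
    entries: List[SequenceEntry] = []
    counters: Dict[str, int] = {}
    seen: set = set()
    for _, row in table.iterrows():
        fname = str(row["file"]).strip()
        seq_id = str(row["sequence"]).strip() if "sequence" in cols and pd.notna(row.get("sequence")) else seq_default
        acq = None
        if "acquisition_time" in cols and pd.notna(row.get("acquisition_time")):
            acq = datetime.fromisoformat(str(row["acquisition_time"]).strip())
        fpath = Path(fname)
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        if fpath in seen:
            warnings.warn(f"{path}: duplicate file entry {fname!r} kept", stacklevel=2)
        seen.add(fpath)
        counters[seq_id] = counters.get(seq_id, 0) + 1
        entries.append(
            SequenceEntry(
                file_path=fpath,
                sequence_id=seq_id,
                order_index=counters[seq_id],
                acquisition_time=acq,
                missing=check_exists and not fpath.exists(),
            )
        )
    return entries


def categorize_samples(
    entries: Sequence[SequenceEntry], separator: str = "_"
) -> List[SampleCategory]:
    """Group entries into sample-type categories by filename prefix.

    The category name is the filename stem up to the first occurrence of
    ``separator``. A filename without the separator falls back to its full
    stem (with a warning). The result is a partition of ``entries``, in
    first-appearance order.
    """
    if not separator:
        raise ValueError("separator must be a non-empty string")
    cats: Dict[str, SampleCategory] = {}
    for e in entries:
        stem = e.stem
        if separator in stem:
            name = stem.split(separator, 1)[0]
        else:
            name = stem
            warnings.warn(
                f"file {e.file_path.name!r} lacks separator {separator!r}; "
                f"using full stem as its category",
                stacklevel=2,
            )
        cats.setdefault(name, SampleCategory(name)).members.append(e)
    out = list(cats.values())
    for c in out:
        log.info("category %s: %d file(s)", c.name, len(c))
    return out


# ---------------------------------------------------------------------------
# mzXML

#: Median per-scan centroid count beyond which a profile-mode warning fires.
PROFILE_MODE_PEAKCOUNT = 5000


def read_mzxml(path: Path | str) -> CentroidRun:
    """Load MS¹ scans of a centroided mzXML file.

    Handles 32/64-bit network-byte-order peak blobs with optional zlib
    compression and ISO-8601 duration retention times. Scans whose decoded
    array length disagrees with the declared ``peaksCount`` raise
    :class:`MzXMLError` naming the scan.
    """
    path = Path(path)
    rts: List[float] = []
    mzs: List[np.ndarray] = []
    intens: List[np.ndarray] = []
    polarity: Optional[str] = None
    try:
        with _pyteomics_mzxml.MzXML(str(path)) as reader:
            for scan in reader:
                if int(scan.get("msLevel", 1)) != 1:
                    continue
                num = scan.get("num", "?")
                try:
                    mz = np.asarray(scan["m/z array"], dtype=np.float64)
                    iy = np.asarray(scan["intensity array"], dtype=np.float64)
                except Exception as exc:  # undecodable blob
                    raise MzXMLError(f"{path}: scan {num}: cannot decode peaks ({exc})") from exc
                declared = scan.get("peaksCount")
                if declared is not None and int(declared) != len(mz):
                    raise MzXMLError(
                        f"{path}: scan {num}: peaksCount {declared} != decoded {len(mz)}"
                    )
                rt = scan.get("retentionTime")
                if rt is None:
                    raise MzXMLError(f"{path}: scan {num}: missing retentionTime")
                rt_s = float(rt) * 60.0 if getattr(rt, "unit_info", None) == "minute" else float(rt)
                order = np.argsort(mz, kind="stable")
                if not np.all(order == np.arange(len(mz))):
                    mz, iy = mz[order], iy[order]
                rts.append(rt_s)
                mzs.append(mz)
                intens.append(iy)
                polarity = scan.get("polarity", polarity)
    except MzXMLError:
        raise
    except Exception as exc:
        raise MzXMLError(f"{path}: not a readable mzXML file ({exc})") from exc
    if not rts:
        raise MzXMLError(f"{path}: no MS1 scans found")
    counts = [len(a) for a in mzs]
    if np.median(counts) > PROFILE_MODE_PEAKCOUNT:
        warnings.warn(
            f"{path}: median of {int(np.median(counts))} peaks per scan — "
            f"data may be profile mode; centroided input is required",
            stacklevel=2,
        )
    return CentroidRun(
        rts=np.asarray(rts, dtype=np.float64),
        mzs=mzs,
        intensities=intens,
        polarity=polarity,
        source_path=path,
    )


# ---------------------------------------------------------------------------
# target tables


def read_targets(
    path: Path | str,
    extra_ions: Optional[Mapping[str, chem.IonSpecies]] = None,
) -> List[TargetFeature]:
    """Read a target-feature table (CSV, or TSV for ``.tsv``/``.txt`` files).

    Expected tR is given in minutes and converted to seconds. When a formula
    is present the theoretical m/z is resolved through the formula and ion
    species; a stated target m/z is cross-checked against it (0.001 Da).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    table.columns = [c.strip().lower() for c in table.columns]
    required = {"name", "ion", "expected_tr_min"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"{path}: target table needs columns {sorted(required)} "
            f"(plus 'formula' and/or 'target_mz'); found {list(table.columns)}"
        )
    targets: List[TargetFeature] = []
    for i, row in table.iterrows():
        name = str(row["name"]).strip()
        formula_txt = row.get("formula")
        formula = (
            chem.parse_formula(str(formula_txt).strip())
            if pd.notna(formula_txt) and str(formula_txt).strip()
            else None
        )
        mz_txt = row.get("target_mz")
        target_mz = float(mz_txt) if pd.notna(mz_txt) and str(mz_txt).strip() else None
        ion = chem.get_ion(str(row["ion"]).strip(), extra_ions)
        rt_min = float(row["expected_tr_min"])
        group = row.get("group")
        group = str(group).strip() if pd.notna(group) and str(group).strip() else None
        try:
            targets.append(
                TargetFeature(
                    name=name,
                    ion=ion,
                    expected_rt_s=rt_min * 60.0,
                    formula=formula,
                    target_mz=target_mz,
                    group=group,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: row {i + 1}: {exc}") from exc
    return targets


# ---------------------------------------------------------------------------
# tabular output


def results_table(results: Sequence) -> pd.DataFrame:
    """Flatten FeatureResult objects into one detail DataFrame.

    Retention times and deviations appear in minutes; missing measurements
    stay as empty cells rather than being dropped.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "feature": r.feature.name,
                "ion": r.feature.ion.label,
                "sequence": r.entry.sequence_id,
                "order_index": r.entry.order_index,
                "file": r.entry.file_path.name,
                "category": r.category,
                "found": r.found,
                "tR_min": r.rt_s / 60.0 if r.rt_s is not None else np.nan,
                "tR_dev_min": r.rt_dev_s / 60.0 if r.rt_dev_s is not None else np.nan,
                "mz": r.mz if r.mz is not None else np.nan,
                "ppm_error": r.ppm_error if r.ppm_error is not None else np.nan,
                "area": r.area if r.area is not None else np.nan,
                "area_bias_pct": r.area_bias_pct if r.area_bias_pct is not None else np.nan,
                "ria": r.ria if r.ria is not None else np.nan,
                "zone_tR": r.zones.get("rt", "missing"),
                "zone_mz": r.zones.get("ppm", "missing"),
                "zone_area": r.zones.get("area", "missing"),
            }
        )
    return pd.DataFrame(rows)


_PARAM_COLUMNS = {
    "tR": ["tR_min", "tR_dev_min", "zone_tR"],
    "mz": ["mz", "ppm_error", "zone_mz"],
    "area": ["area", "area_bias_pct", "zone_area"],
    "ria": ["ria"],
}


def write_results(results: Sequence, stats: pd.DataFrame, out_dir: Path | str) -> Dict[str, Path]:
    """Write per-parameter detail CSVs plus the summary CSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    detail = results_table(results)
    written: Dict[str, Path] = {}
    base = ["feature", "ion", "sequence", "order_index", "file", "category", "found"]
    for param, cols in _PARAM_COLUMNS.items():
        p = out_dir / f"results_{param}.csv"
        detail[base + cols].to_csv(p, index=False)
        written[param] = p
    p = out_dir / "results_all.csv"
    detail.to_csv(p, index=False)
    written["all"] = p
    p = out_dir / "summary.csv"
    stats.to_csv(p, index=False)
    written["summary"] = p
    return written
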