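"""Synthetic multi-sequence LC-HRMS campaigns with known ground truth.

The generator emulates the situations a QC screener must detect: one or more
measurement sequences of blank / standard-QC / matrix-QC / sample injections,
each run holding centroided MS¹ scans on a fixed scan grid. Every target
compound contributes a Gaussian chromatographic peak plus its first carbon
isotopolog (M+1) companion at the theoretical abundance ratio. Defects are
injectable per sequence: a detector-sensitivity factor, a linear retention
time drift (seconds per file) and a linear mass-axis drift (ppm across the
sequence). Centroid m/z values additionally carry Gaussian ppm jitter, and a
uniform noise floor of random centroids exercises the peak picker's SNR
filtering.

The written mzXML is deterministic: the same spec and seed reproduce
byte-identical files.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import chem
from .io_formats import CentroidRun

__all__ = [
    "SyntheticFeature",
    "SequenceSpec",
    "CampaignSpec",
    "default_campaign",
    "qc_standard_campaign",
    "simulate_run",
    "write_mzxml",
    "write_campaign",
]

#: QC standard mix used by the default campaign: name, formula,
#: expected tR (min), apex intensity (counts) at sensitivity 1.
_QC_STANDARDS = [
    ("Ferulic acid", "C10H10O4", 14.6, 8.0e4),
    ("Jasmonic acid", "C12H18O3", 21.4, 6.0e4),
    ("Caffeic acid", "C9H8O4", 11.3, 9.0e4),
    ("Tryptamine", "C10H12N2", 8.33, 1.2e5),
    ("Equisetin", "C22H31NO4", 32.1, 5.0e4),
    ("D-pantothenic acid", "C9H17NO5", 6.31, 7.0e4),
    ("2,5-Dihydroxybenzoic acid", "C7H6O4", 9.47, 1.0e5),
    ("Quercetin-3-O-glucopyranoside", "C21H20O12", 16.6, 4.0e4),
]


@dataclass(frozen=True)
class SyntheticFeature:
    """One simulated analyte: formula, ion species, elution and abundance."""

    name: str
    formula: str
    ion_label: str = "[M+H]+"
    rt_s: float = 600.0
    sigma_s: float = 5.0
    apex_intensity: float = 1.0e5
    tailing: float = 0.0  # optional exponential tail time constant, seconds

    @property
    def theoretical_mz(self) -> float:
        ion = chem.get_ion(self.ion_label)
        return chem.adduct_mz(chem.monoisotopic_mass(self.formula), ion)

    @property
    def theoretical_ria(self) -> float:
        return chem.theoretical_ria(self.formula)


@dataclass(frozen=True)
class SequenceSpec:
    """One measurement sequence: file counts per category and its defects.

    ``mz_drift_ppm`` is a (start, end) pair interpolated linearly over the
    files of the sequence, or an explicit per-file tuple for piecewise
    drifts. ``rt_drift_s_per_file`` shifts all peaks by that many seconds
    per file position. ``sensitivity_factor`` scales every apex intensity.
    """

    name: str
    categories: Tuple[Tuple[str, int], ...] = (("blank", 2), ("QCstd", 12), ("matrixQC", 2), ("sample", 6))
    sensitivity_factor: float = 1.0
    rt_drift_s_per_file: float = 0.0
    mz_drift_ppm: Tuple[float, ...] = (0.0, 0.0)

    def layout(self) -> List[Tuple[str, int]]:
        """Measurement order: categories interleaved round-robin, with the
        per-category running number (1-based) attached."""
        pools = [(cat, n) for cat, n in self.categories]
        counters = {cat: 0 for cat, _ in pools}
        remaining = {cat: n for cat, n in pools}
        order: List[Tuple[str, int]] = []
        while any(remaining.values()):
            for cat, _ in pools:
                if remaining[cat] > 0:
                    counters[cat] += 1
                    remaining[cat] -= 1
                    order.append((cat, counters[cat]))
        return order

    @property
    def n_files(self) -> int:
        return sum(n for _, n in self.categories)

    def ppm_shift(self, file_index: int) -> float:
        """Injected mass-axis shift (ppm) of the file at 0-based position."""
        n = self.n_files
        d = self.mz_drift_ppm
        if len(d) == n:
            return float(d[file_index])
        start, end = d[0], d[-1]
        if n <= 1:
            return float(start)
        return float(start + (end - start) * file_index / (n - 1))


@dataclass(frozen=True)
class CampaignSpec:
    """A complete synthetic campaign; the seed fully determines the output."""

    features: Tuple[SyntheticFeature, ...]
    sequences: Tuple[SequenceSpec, ...]
    scan_interval_s: float = 1.0
    rt_min_s: float = 0.0
    rt_max_s: Optional[float] = None  # default: last peak + 60 s
    mz_jitter_ppm: float = 0.5
    #: run-to-run injection repeatability: lognormal σ of the per-file scale
    file_scale_sigma: float = 0.03
    #: per-centroid multiplicative intensity noise (relative σ)
    intensity_jitter_rel: float = 0.02
    noise_peaks_per_scan: float = 10.0
    noise_intensity_mean: float = 200.0
    noise_mz_range: Tuple[float, float] = (100.0, 600.0)
    #: per-category intensity scale; categories absent here default to 1
    category_scale: Tuple[Tuple[str, float], ...] = (("blank", 0.0),)
    seed: int = 20150

    def rt_grid(self) -> np.ndarray:
        hi = self.rt_max_s
        if hi is None:
            hi = max(f.rt_s for f in self.features) + 60.0
        n = int(np.floor((hi - self.rt_min_s) / self.scan_interval_s)) + 1
        return self.rt_min_s + self.scan_interval_s * np.arange(n)

    def scale_for(self, category: str) -> float:
        return dict(self.category_scale).get(category, 1.0)


def default_campaign(seed: int = 20150, **overrides) -> CampaignSpec:
    """Two measurement sequences of a QC-standard mix, blanks, matrix QCs and
    samples, with no injected defects."""
    features = tuple(
        SyntheticFeature(name=n, formula=f, rt_s=tr * 60.0, sigma_s=5.0, apex_intensity=a)
        for n, f, tr, a in _QC_STANDARDS
    )
    sequences = (SequenceSpec(name="sequence1"), SequenceSpec(name="sequence2"))
    return CampaignSpec(features=features, sequences=sequences, seed=seed, **overrides)


def qc_standard_campaign(
    seed: int = 20150,
    n_qc_per_sequence: int = 12,
    sensitivity_factors: Tuple[float, float] = (1.0, 2.0),
    mz_drift_ppm: Tuple[float, float] = (-5.0, 5.0),
    features: Optional[Sequence[SyntheticFeature]] = None,
    **overrides,
) -> CampaignSpec:
    """The two-sequence QC-standard scenario with injected defects.

    Sequence 1 is nominal; sequence 2 carries a detector sensitivity step
    (default 2×) and a linear mass-axis drift (default −5 → +5 ppm) across
    its files — the kind of inter-sequence offset and within-sequence drift
    a QC screen must surface.
    """
    if features is None:
        features = tuple(
            SyntheticFeature(name=n, formula=f, rt_s=tr * 60.0, sigma_s=5.0, apex_intensity=a)
            for n, f, tr, a in _QC_STANDARDS
        )
    sequences = (
        SequenceSpec(
            name="sequence1",
            categories=(("QCstd", n_qc_per_sequence),),
            sensitivity_factor=sensitivity_factors[0],
        ),
        SequenceSpec(
            name="sequence2",
            categories=(("QCstd", n_qc_per_sequence),),
            sensitivity_factor=sensitivity_factors[1],
            mz_drift_ppm=mz_drift_ppm,
        ),
    )
    return CampaignSpec(features=tuple(features), sequences=sequences, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# simulation


def _peak_profile(rts: np.ndarray, rt0: float, sigma: float, amp: float, tail: float) -> np.ndarray:
    g = amp * np.exp(-0.5 * ((rts - rt0) / sigma) ** 2)
    if tail > 0:
        # exponentially modified tail via convolution on the scan grid
        dt = rts[1] - rts[0] if len(rts) > 1 else 1.0
        kernel_t = np.arange(0, 5 * tail + dt, dt)
        kernel = np.exp(-kernel_t / tail)
        kernel /= kernel.sum()
        g = np.convolve(g, kernel)[: len(rts)]
    return g


def file_scale_jitter(spec: CampaignSpec, sequence_index: int, file_index: int) -> float:
    """The realized per-file injection-repeatability factor (lognormal).

    Keyed on its own RNG stream so the ground truth can be reconstructed
    without regenerating the spectra.
    """
    rng = np.random.default_rng([spec.seed, sequence_index, file_index, 1])
    return float(rng.lognormal(0.0, spec.file_scale_sigma)) if spec.file_scale_sigma > 0 else 1.0


def simulate_run(spec: CampaignSpec, sequence_index: int, file_index: int) -> CentroidRun:
    """Generate the centroided run at a given (sequence, file) position.

    ``file_index`` is the 0-based position in the sequence's measurement
    order (see :meth:`SequenceSpec.layout`). The RNG stream is keyed on
    (seed, sequence, file), so any single run can be regenerated without
    simulating the rest of the campaign.
    """
    seq = spec.sequences[sequence_index]
    category, _ = seq.layout()[file_index]
    rng = np.random.default_rng([spec.seed, sequence_index, file_index])
    rts = spec.rt_grid()
    n = len(rts)
    scale = seq.sensitivity_factor * spec.scale_for(category) * file_scale_jitter(spec, sequence_index, file_index)
    ppm_shift = seq.ppm_shift(file_index)
    rt_shift = seq.rt_drift_s_per_file * file_index

    mz_rows: List[List[float]] = [[] for _ in range(n)]
    iy_rows: List[List[float]] = [[] for _ in range(n)]

    for feat in spec.features:
        if scale <= 0:
            continue
        profile = _peak_profile(rts, feat.rt_s + rt_shift, feat.sigma_s, feat.apex_intensity * scale, feat.tailing)
        idx = np.nonzero(profile > 1.0)[0]
        mz0 = feat.theoretical_mz
        mz1 = mz0 + chem.C13_C12_DELTA
        ria = feat.theoretical_ria
        jit0 = rng.normal(0.0, spec.mz_jitter_ppm, size=len(idx))
        jit1 = rng.normal(0.0, spec.mz_jitter_ppm, size=len(idx))
        amp0 = 1.0 + rng.normal(0.0, spec.intensity_jitter_rel, size=len(idx))
        amp1 = 1.0 + rng.normal(0.0, spec.intensity_jitter_rel, size=len(idx))
        for j, i in enumerate(idx):
            mz_rows[i].append(mz0 * (1.0 + (ppm_shift + jit0[j]) * 1e-6))
            iy_rows[i].append(profile[i] * max(amp0[j], 0.0))
            mz_rows[i].append(mz1 * (1.0 + (ppm_shift + jit1[j]) * 1e-6))
            iy_rows[i].append(profile[i] * ria * max(amp1[j], 0.0))

    # noise floor: Poisson number of uniform-m/z centroids, exponential intensity
    lo, hi = spec.noise_mz_range
    counts = rng.poisson(spec.noise_peaks_per_scan, size=n)
    for i in range(n):
        k = int(counts[i])
        if k == 0:
            continue
        mz_rows[i].extend(rng.uniform(lo, hi, size=k))
        iy_rows[i].extend(rng.exponential(spec.noise_intensity_mean, size=k))

    mzs: List[np.ndarray] = []
    iys: List[np.ndarray] = []
    for i in range(n):
        mz = np.asarray(mz_rows[i], dtype=np.float64)
        iy = np.asarray(iy_rows[i], dtype=np.float64)
        order = np.argsort(mz, kind="stable")
        mzs.append(mz[order])
        iys.append(iy[order])
    return CentroidRun(rts=rts, mzs=mzs, intensities=iys, polarity="+")


# ---------------------------------------------------------------------------
# mzXML writing


def _encode_peaks(mz: np.ndarray, iy: np.ndarray, precision: int, compression: Optional[str]) -> str:
    dtype = ">f8" if precision == 64 else ">f4"
    pairs = np.empty(2 * len(mz), dtype=dtype)
    pairs[0::2] = mz
    pairs[1::2] = iy
    raw = pairs.tobytes()
    if compression == "zlib":
        raw = zlib.compress(raw, level=6)
    return base64.b64encode(raw).decode("ascii")


def write_mzxml(
    path: Path | str,
    run: CentroidRun,
    precision: int = 64,
    compression: Optional[str] = None,
) -> Path:
    """Write a centroided run as mzXML (network byte order, optional zlib).

    Output is fully deterministic — no timestamps, fixed float formatting —
    so identical runs produce byte-identical files.
    """
    if precision not in (32, 64):
        raise ValueError("precision must be 32 or 64")
    if compression not in (None, "zlib"):
        raise ValueError("compression must be None or 'zlib'")
    path = Path(path)
    comp_attr = "zlib" if compression == "zlib" else "none"
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{run.n_scans}">',
    ]
    pol = f' polarity="{run.polarity}"' if run.polarity else ""
    for i in range(run.n_scans):
        mz, iy = run.mzs[i], run.intensities[i]
        b64 = _encode_peaks(mz, iy, precision, compression)
        lines.append(
            f'  <scan num="{i + 1}" msLevel="1" peaksCount="{len(mz)}"'
            f' retentionTime="PT{run.rts[i]:.6f}S"{pol} scanType="Full">'
        )
        lines.append(
            f'   <peaks precision="{precision}" byteOrder="network"'
            f' contentType="m/z-int" compressionType="{comp_attr}">{b64}</peaks>'
        )
        lines.append("  </scan>")
    lines.append(" </msRun>")
    lines.append("</mzXML>")
    path.write_text("\n".join(lines) + "\n", encoding="ascii")
    return path


def write_campaign(spec: CampaignSpec, out_dir: Path | str, force: bool = False) -> Dict:
    """Write the whole campaign: mzXML files, one sequence CSV per sequence,
    and a ground-truth JSON recording every injected value.

    Files are laid out as ``<out>/<sequence>/<category>_<nn>.mzXML`` so that
    filename-prefix categorisation (separator ``_``) groups them. Returns the
    ground-truth dictionary (also written to ``ground_truth.json``).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: Dict = {
        "seed": spec.seed,
        "scan_interval_s": spec.scan_interval_s,
        "mz_jitter_ppm": spec.mz_jitter_ppm,
        "features": [
            {
                "name": f.name,
                "formula": f.formula,
                "ion": f.ion_label,
                "rt_s": f.rt_s,
                "sigma_s": f.sigma_s,
                "apex_intensity": f.apex_intensity,
                "theoretical_mz": f.theoretical_mz,
                "theoretical_ria": f.theoretical_ria,
                "gaussian_area": f.apex_intensity * f.sigma_s * float(np.sqrt(2.0 * np.pi)),
            }
            for f in spec.features
        ],
        "sequences": [],
    }
    for s_idx, seq in enumerate(spec.sequences):
        seq_dir = out_dir / seq.name
        seq_dir.mkdir(exist_ok=True)
        csv_lines = ["file,sequence"]
        files = []
        for f_idx, (category, nn) in enumerate(seq.layout()):
            fname = f"{category}_{nn:02d}.mzXML"
            run = simulate_run(spec, s_idx, f_idx)
            write_mzxml(seq_dir / fname, run)
            csv_lines.append(f"{seq.name}/{fname},{seq.name}")
            files.append(
                {
                    "file": f"{seq.name}/{fname}",
                    "category": category,
                    "order_index": f_idx + 1,
                    "ppm_shift": seq.ppm_shift(f_idx),
                    "rt_shift_s": seq.rt_drift_s_per_file * f_idx,
                    "intensity_scale": seq.sensitivity_factor * spec.scale_for(category),
                    "file_scale_jitter": file_scale_jitter(spec, s_idx, f_idx),
                }
            )
        (out_dir / f"{seq.name}.csv").write_text("\n".join(csv_lines) + "\n", encoding="utf-8")
        truth["sequences"].append(
            {
                "name": seq.name,
                "sensitivity_factor": seq.sensitivity_factor,
                "rt_drift_s_per_file": seq.rt_drift_s_per_file,
                "files": files,
            }
        )
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return truth
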