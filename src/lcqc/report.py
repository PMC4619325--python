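"""Coloured quality overview and per-parameter illustrations.

The overview is a features × files matrix; every cell shows the measured
retention time, m/z and area together with their deviations, each flagged
with one of four colour zones (plus grey for missing). It is written both as
an HTML page and as a machine-readable CSV twin carrying the zone codes as
text, so the colours survive colour-blind readers and automated checks.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from jinja2 import Template

from .pipeline import ScreenOutcome
from .qc_metrics import FeatureResult, ToleranceScheme

__all__ = ["render_overview", "render_parameter_plots"]

ZONE_COLOURS = {
    "green": "#4daf4a",
    "yellow": "#ffd92f",
    "orange": "#ff7f00",
    "red": "#e41a1c",
    "missing": "#bdbdbd",
}

_OVERVIEW_TEMPLATE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>QC overview</title>
<style>
 body { font-family: sans-serif; font-size: 11px; }
 table { border-collapse: collapse; }
 th, td { border: 1px solid #999; padding: 2px 4px; text-align: right; }
 th.feat { text-align: left; }
 .zone { font-weight: bold; }
</style></head>
<body>
<h1>Coloured quality overview</h1>
<p>{{ n_features }} feature(s) × {{ n_files }} file(s). Zones:
{% for z, c in colours.items() %}<span style="background:{{ c }}">&nbsp;{{ z }}&nbsp;</span> {% endfor %}
</p>
<table>
<tr><th class="feat">feature</th>
{% for f in files %}<th>{{ f }}</th>{% endfor %}
<th>mean tR (min)</th><th>mean m/z</th><th>mean area</th></tr>
{% for row in rows %}
<tr><th class="feat">{{ row.label }}</th>
{% for cell in row.cells %}
<td>
 <div class="zone" data-zone="{{ cell.zone_rt }}" style="background:{{ colours[cell.zone_rt] }}">tR {{ cell.rt }} ({{ cell.rt_dev }})</div>
 <div class="zone" data-zone="{{ cell.zone_ppm }}" style="background:{{ colours[cell.zone_ppm] }}">m/z {{ cell.mz }} ({{ cell.ppm }} ppm)</div>
 <div class="zone" data-zone="{{ cell.zone_area }}" style="background:{{ colours[cell.zone_area] }}">area {{ cell.area }} ({{ cell.area_bias }} %)</div>
</td>
{% endfor %}
<td>{{ row.mean_rt }}</td><td>{{ row.mean_mz }}</td><td>{{ row.mean_area }}</td>
</tr>
{% endfor %}
</table>
</body></html>
"""
)


def _fmt(value: Optional[float], digits: int = 2) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return "—"
    return f"{value:.{digits}f}"


def _ordered_files(results: Sequence[FeatureResult], x_axis: str = "order") -> List[Tuple[str, str]]:
    """Unique (sequence id, file name) column keys in measurement order.

    The same file name may legitimately recur in different sequences, so the
    sequence id is part of the column identity.
    """
    seen: Dict[Tuple[str, str], tuple] = {}
    for i, r in enumerate(results):
        col = (r.entry.sequence_id, r.entry.file_path.name)
        if col not in seen:
            if x_axis == "time" and r.entry.acquisition_time is not None:
                key = (r.entry.acquisition_time, i)
            else:
                key = (i,)
            seen[col] = key
    return [c for c, _ in sorted(seen.items(), key=lambda kv: kv[1])]


def render_overview(
    outcome: ScreenOutcome,
    out_dir: Path | str,
    x_axis: str = "order",
) -> Tuple[Path, Path]:
    """Write ``overview.html`` and its CSV twin ``overview_zones.csv``.

    Returns the two paths. Column order follows the measurement order, or
    acquisition time when ``x_axis='time'`` and timestamps are present.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = outcome.results
    files = _ordered_files(results, x_axis)
    feats = list(dict.fromkeys((r.feature.name, r.feature.ion.label) for r in results))
    by_cell = {
        (r.feature.name, r.feature.ion.label, r.entry.sequence_id, r.entry.file_path.name): r
        for r in results
    }

    rows = []
    csv_rows = []
    for feat_key in feats:
        cells = []
        found_rt, found_mz, found_area = [], [], []
        for seq_id, fname in files:
            r = by_cell.get((*feat_key, seq_id, fname))
            if r is None:
                cell = dict(
                    rt="—", rt_dev="—", mz="—", ppm="—", area="—", area_bias="—",
                    zone_rt="missing", zone_ppm="missing", zone_area="missing",
                )
            else:
                cell = dict(
                    rt=_fmt(r.rt_s / 60.0 if r.rt_s is not None else None),
                    rt_dev=_fmt(r.rt_dev_s / 60.0 if r.rt_dev_s is not None else None),
                    mz=_fmt(r.mz, 4),
                    ppm=_fmt(r.ppm_error),
                    area=_fmt(r.area, 0),
                    area_bias=_fmt(r.area_bias_pct, 1),
                    zone_rt=r.zones.get("rt", "missing"),
                    zone_ppm=r.zones.get("ppm", "missing"),
                    zone_area=r.zones.get("area", "missing"),
                )
                if r.found:
                    if r.rt_s is not None:
                        found_rt.append(r.rt_s / 60.0)
                    if r.mz is not None:
                        found_mz.append(r.mz)
                    if r.area is not None:
                        found_area.append(r.area)
            cells.append(cell)
            csv_rows.append(
                {
                    "feature": feat_key[0],
                    "ion": feat_key[1],
                    "sequence": seq_id,
                    "file": fname,
                    "zone_tR": cell["zone_rt"],
                    "zone_mz": cell["zone_ppm"],
                    "zone_area": cell["zone_area"],
                }
            )
        rows.append(
            dict(
                label=f"{feat_key[0]} {feat_key[1]}",
                cells=cells,
                mean_rt=_fmt(float(np.mean(found_rt)) if found_rt else None),
                mean_mz=_fmt(float(np.mean(found_mz)) if found_mz else None, 4),
                mean_area=_fmt(float(np.mean(found_area)) if found_area else None, 0),
            )
        )

    html = _OVERVIEW_TEMPLATE.render(
        rows=rows, files=[f"{s}: {n}" for s, n in files], colours=ZONE_COLOURS,
        n_features=len(feats), n_files=len(files),
    )
    html_path = out_dir / "overview.html"
    html_path.write_text(html, encoding="utf-8")
    csv_path = out_dir / "overview_zones.csv"
    pd.DataFrame(csv_rows).to_csv(csv_path, index=False)
    return html_path, csv_path


# ---------------------------------------------------------------------------
# plots


def _zone_bands(ax, limits: Tuple[float, float, float], axis: str = "y") -> None:
    """Shade the four tolerance zones as horizontal (or vertical) bands."""
    g, y, o = limits
    spans = [
        (-g, g, ZONE_COLOURS["green"]),
        (g, y, ZONE_COLOURS["yellow"]),
        (-y, -g, ZONE_COLOURS["yellow"]),
        (y, o, ZONE_COLOURS["orange"]),
        (-o, -y, ZONE_COLOURS["orange"]),
        (o, o * 1.5, ZONE_COLOURS["red"]),
        (-o * 1.5, -o, ZONE_COLOURS["red"]),
    ]
    for lo, hi, c in spans:
        if axis == "y":
            ax.axhspan(lo, hi, color=c, alpha=0.15, lw=0)
        else:
            ax.axvspan(lo, hi, color=c, alpha=0.15, lw=0)


def _x_positions(results: List[FeatureResult], x_axis: str) -> Tuple[np.ndarray, str]:
    if x_axis == "time" and all(r.entry.acquisition_time is not None for r in results):
        t0 = min(r.entry.acquisition_time for r in results)
        xs = np.array([(r.entry.acquisition_time - t0).total_seconds() / 60.0 for r in results])
        return xs, "acquisition time (min)"
    order = {c: i + 1 for i, c in enumerate(_ordered_files(results))}
    return (
        np.array([order[(r.entry.sequence_id, r.entry.file_path.name)] for r in results]),
        "measurement order",
    )


def render_parameter_plots(
    outcome: ScreenOutcome,
    out_dir: Path | str,
    scheme: Optional[ToleranceScheme] = None,
    x_axis: str = "order",
    image_format: str = "png",
    ria: bool = False,
) -> List[Path]:
    """Per-feature illustrations: EIC overlay, area / tR / m/z-vs-order plots
    with tolerance bands, per-category boxplots, and (optionally) RIA.

    Features sharing a ``group`` label are overlaid in one retention-time
    plot. Returns the list of written image paths.
    """
    scheme = scheme or ToleranceScheme()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    feats = list(dict.fromkeys((r.feature.name, r.feature.ion.label) for r in outcome.results))
    by_feat: Dict[tuple, List[FeatureResult]] = {k: [] for k in feats}
    for r in outcome.results:
        by_feat[(r.feature.name, r.feature.ion.label)].append(r)

    def save(fig, stem: str) -> None:
        p = out_dir / f"{stem}.{image_format}"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)

    for feat_key, rows in by_feat.items():
        slug = f"{feat_key[0]}_{feat_key[1]}".replace(" ", "-").replace("/", "-")
        target = rows[0].feature
        xs, xlabel = _x_positions(rows, x_axis)
        found = [(x, r) for x, r in zip(xs, rows) if r.found]

        # (a) EIC overlay, legend "F<n> <file>"
        fig, ax = plt.subplots(figsize=(7, 4))
        for i, (x, r) in enumerate(zip(xs, rows)):
            key = (feat_key[0], feat_key[1], r.entry.sequence_id, r.entry.file_path.name)
            if key in outcome.eics:
                rt, inten = outcome.eics[key]
                lo = target.expected_rt_s - 90.0
                hi = target.expected_rt_s + 90.0
                m = (rt >= lo) & (rt <= hi)
                ax.plot(rt[m] / 60.0, inten[m], lw=0.8, label=f"F{int(x)} {r.entry.file_path.name}")
        ax.set_xlabel("retention time (min)")
        ax.set_ylabel("intensity (counts)")
        ax.set_title(f"EIC overlay — {feat_key[0]} {feat_key[1]}")
        if len(rows) <= 30:
            ax.legend(fontsize=5, ncol=2)
        save(fig, f"eic_{slug}")

        # (b) area vs order with bias bands
        fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
        if found:
            fx = [x for x, r in found]
            axes[0].plot(fx, [r.area for _, r in found], "o-", ms=4)
            axes[1].plot(fx, [r.area_bias_pct if r.area_bias_pct is not None else np.nan for _, r in found], "o", ms=4)
        axes[0].set_ylabel("feature area (counts·s)")
        _zone_bands(axes[1], scheme.area_limits_pct)
        axes[1].set_ylabel("area bias (%)")
        axes[1].set_xlabel(xlabel)
        axes[0].set_title(f"Feature area — {feat_key[0]} {feat_key[1]}")
        save(fig, f"area_{slug}")

        # (c) tR vs order; same-group ion species overlaid
        fig, ax = plt.subplots(figsize=(7, 4))
        group = target.group
        members = [feat_key] + [
            k for k in feats
            if k != feat_key and group is not None and by_feat[k][0].feature.group == group
        ]
        for k in members:
            mrows = by_feat[k]
            mx, _ = _x_positions(mrows, x_axis)
            pts = [(x, r.rt_s / 60.0) for x, r in zip(mx, mrows) if r.found and r.rt_s is not None]
            if pts:
                ax.plot(*zip(*pts), "o-", ms=4, label=f"{k[0]} {k[1]}")
        ax.axhline(target.expected_rt_s / 60.0, color="k", ls="--", lw=0.8, label="expected tR")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("tR (min)")
        ax.set_title(f"Retention time — {feat_key[0]} {feat_key[1]}")
        ax.legend(fontsize=6)
        save(fig, f"rt_{slug}")

        # (d) m/z and ppm vs order with mean ± SD and tolerance bands
        fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
        if found:
            fx = [x for x, r in found]
            mzv = np.array([r.mz for _, r in found], dtype=float)
            axes[0].plot(fx, mzv, "o", ms=4)
            mu, sd = float(np.mean(mzv)), float(np.std(mzv, ddof=1)) if len(mzv) > 1 else 0.0
            axes[0].axhline(mu, color="k", lw=0.8)
            axes[0].axhspan(mu - sd, mu + sd, color="k", alpha=0.1, lw=0)
            axes[1].plot(fx, [r.ppm_error if r.ppm_error is not None else np.nan for _, r in found], "o", ms=4)
        axes[0].axhline(target.theoretical_mz, color="b", ls="--", lw=0.8)
        axes[0].set_ylabel("measured m/z")
        _zone_bands(axes[1], scheme.ppm_limits)
        axes[1].set_ylabel("mass accuracy (ppm)")
        axes[1].set_xlabel(xlabel)
        axes[0].set_title(f"m/z and mass accuracy — {feat_key[0]} {feat_key[1]}")
        save(fig, f"mz_{slug}")

        # (e) RIA vs order, only when enabled
        if ria:
            fig, ax = plt.subplots(figsize=(7, 4))
            pts = [(x, r.ria) for x, r in found if r.ria is not None]
            if pts:
                ax.plot(*zip(*pts), "o", ms=4)
            t_ria = target.theoretical_ria
            if t_ria is not None:
                ax.axhline(t_ria, color="b", ls="--", lw=0.8, label="theoretical RIA")
                ax.legend(fontsize=6)
            ax.set_xlabel(xlabel)
            ax.set_ylabel("RIA (M+1 / M)")
            ax.set_title(f"Relative isotopolog abundance — {feat_key[0]} {feat_key[1]}")
            save(fig, f"ria_{slug}")

        # per-category boxplots for area, tR, m/z
        fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
        cats = list(dict.fromkeys(r.category for r in rows))
        for ax, (label, getter) in zip(
            axes,
            (
                ("area", lambda r: r.area),
                ("tR (min)", lambda r: r.rt_s / 60.0 if r.rt_s is not None else None),
                ("m/z", lambda r: r.mz),
            ),
        ):
            data, labels = [], []
            for c in cats:
                vals = [getter(r) for r in rows if r.category == c and r.found and getter(r) is not None]
                if vals:
                    data.append(vals)
                    labels.append(c)
            if data:
                ax.boxplot(data, tick_labels=labels)
            ax.set_ylabel(label)
            ax.tick_params(axis="x", labelsize=6, rotation=30)
        fig.suptitle(f"Per-category precision — {feat_key[0]} {feat_key[1]}", fontsize=9)
        fig.tight_layout()
        save(fig, f"box_{slug}")

    return written
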