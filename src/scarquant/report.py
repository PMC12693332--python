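"""Bullseye rendering and clinical report assembly.

Every number in the report is taken verbatim from a computed
:class:`~scarquant.quantify.ScarMetrics`; nothing is recomputed at
render time.  ``report.json`` is the single source of truth and the
HTML document is generated from it.
"""

from __future__ import annotations

import base64
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .quantify import ScarMetrics, SegmentExtent, TransmuralityProfile

__all__ = [
    "ReportDocument",
    "render_bullseye16",
    "render_bullseye_chords",
    "generate_report",
]

_FIXED_TIMESTAMP = "1970-01-01T00:00:00Z"

# Idealized display layout: ring index (0 = innermost) and angular span
# per AHA segment, anchored with the anterior-insertion ray at 60 deg.
_RING_OF = {**{s: 2 for s in range(1, 7)}, **{s: 1 for s in range(7, 13)},
            **{s: 0 for s in range(13, 17)}}


def _segment_display_angles(segment: int) -> tuple[float, float]:
    if segment <= 12:
        k = (segment - 1) % 6  # 0-based CCW position from the anterior segment
        start = 0.0 + 60.0 * k
        return start, start + 60.0
    k = segment - 13
    start = -15.0 + 90.0 * k
    return start, start + 90.0


def render_bullseye16(
    extents: SegmentExtent, path: Optional[str | Path] = None
) -> tuple[bytes, dict]:
    """Render the 16-segment infarct-size bullseye.

    Three concentric rings (base outer, mid middle, apex inner), each
    sector color-mapped on a fixed 0-100% scale with its numeric label;
    segments absent from ``extents`` are hatched.  Returns the PNG bytes
    and the serialized plot data (segment -> percent), which round-trips
    the input exactly.
    """
    data = {int(s): float(v) for s, v in extents.percent.items()}
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    cmap = plt.get_cmap("viridis")
    for seg in range(1, 17):
        ring = _RING_OF[seg]
        r0, r1 = 1.0 + ring, 2.0 + ring
        a0, a1 = _segment_display_angles(seg)
        th = np.radians(np.linspace(a0, a1, 32))
        if seg in data:
            color = cmap(data[seg] / 100.0)
            ax.fill_between(th, r0, r1, color=color)
        else:
            ax.fill_between(th, r0, r1, color="white", hatch="///", edgecolor="gray")
        mid = np.radians((a0 + a1) / 2.0)
        label = f"{data[seg]:.0f}" if seg in data else "–"
        ax.text(mid, (r0 + r1) / 2.0, label, ha="center", va="center", fontsize=8)
        ax.plot(th, np.full_like(th, r1), color="k", lw=0.5)
    ax.set_ylim(0, 4.2)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("Infarct size per AHA segment (%)")
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, 100))
    fig.colorbar(sm, ax=ax, shrink=0.7, label="scar extent (%)")
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    plt.close(fig)
    png = buf.getvalue()
    if path is not None:
        Path(path).write_bytes(png)
    return png, data


def render_bullseye_chords(
    profile: TransmuralityProfile, path: Optional[str | Path] = None
) -> tuple[bytes, dict]:
    """Render the chord-resolution transmurality bullseye.

    One ring per quantified slice (apex innermost, base outermost), 100
    angular bins per ring, color-mapped on a fixed [0, 1] scale.  Returns
    the PNG bytes and the serialized data ``{slice: [100 values]}``.
    """
    slices = sorted(profile.values)
    if not slices:
        raise ValueError("no slice profiles to render")
    data = {int(i): [float(v) for v in profile.values[i]] for i in slices}
    n = len(data[slices[0]])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, n + 1)
    # base (lowest slice index by convention) on the outside
    radii = np.arange(len(slices) + 1, 0, -1)
    grid = np.array([data[i] for i in slices])
    ax.pcolormesh(theta, radii[::-1], grid[::-1], cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("Transmurality (100 chords per slice)")
    sm = plt.cm.ScalarMappable(cmap="viridis", norm=plt.Normalize(0, 1))
    fig.colorbar(sm, ax=ax, shrink=0.7, label="transmurality")
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    plt.close(fig)
    png = buf.getvalue()
    if path is not None:
        Path(path).write_bytes(png)
    return png, data


@dataclass
class ReportDocument:
    """Assembled clinical report: metadata, metrics, provenance, plots."""

    patient_meta: dict
    metrics: ScarMetrics
    provenance: dict
    bullseye16: dict
    bullseye_chords: dict
    timestamp: str

    def to_dict(self) -> dict:
        return {
            "patient": self.patient_meta,
            "metrics": self.metrics.to_dict(),
            "provenance": self.provenance,
            "bullseye_16_segments": {str(k): v for k, v in self.bullseye16.items()},
            "bullseye_chords": {str(k): v for k, v in self.bullseye_chords.items()},
            "created": self.timestamp,
        }


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Scar quantification report</title>
<style>body{{font-family:sans-serif;max-width:60em;margin:2em auto}}
table{{border-collapse:collapse}}td,th{{border:1px solid #999;padding:0.3em 0.8em}}
img{{max-width:28em}}</style></head><body>
<h1>Myocardial scar quantification report</h1>
<p><b>Patient:</b> {patient_id} &nbsp; <b>Study date:</b> {study_date}
&nbsp; <b>Created:</b> {created}</p>
<h2>Global metrics</h2>
<table>
<tr><th>Myocardial volume</th><td>{myo_ml:.2f} mL</td></tr>
<tr><th>Scar volume</th><td>{scar_ml:.2f} mL</td></tr>
<tr><th>Scar mass</th><td>{scar_g:.2f} g</td></tr>
<tr><th>Scar extent</th><td>{extent:.1f} %</td></tr>
<tr><th>Mean transmurality</th><td>{mean_t:.3f}</td></tr>
<tr><th>Max transmurality</th><td>{max_t:.3f}</td></tr>
</table>
<h2>Per-segment scar extent</h2>
<table><tr><th>Segment</th><th>Extent (%)</th><th>Scar px</th><th>Total px</th></tr>
{segment_rows}
</table>
<h2>Bullseye plots</h2>
<img src="data:image/png;base64,{bullseye16}" alt="16-segment bullseye">
<img src="data:image/png;base64,{bullseye_chords}" alt="chord bullseye">
<h2>Provenance</h2>
<pre>{provenance}</pre>
</body></html>
"""


def generate_report(
    meta: dict,
    metrics: ScarMetrics,
    extents: SegmentExtent,
    profile: TransmuralityProfile,
    out_dir: str | Path,
    provenance: Optional[dict] = None,
    timestamp: Optional[str] = None,
) -> ReportDocument:
    """Write ``report.json`` and a self-contained ``report.html``.

    ``timestamp`` defaults to a fixed epoch string so that identical
    inputs produce byte-identical reports; pass a real timestamp for
    clinical use.  Patient metadata defaults to an anonymous patient.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"id": "anonymous", "study_date": "", **(meta or {})}
    provenance = provenance or {}
    timestamp = timestamp or _FIXED_TIMESTAMP

    png16, data16 = render_bullseye16(extents, out_dir / "bullseye_16.png")
    png_ch, data_ch = render_bullseye_chords(profile, out_dir / "bullseye_chords.png")

    doc = ReportDocument(
        patient_meta=meta,
        metrics=metrics,
        provenance=provenance,
        bullseye16=data16,
        bullseye_chords=data_ch,
        timestamp=timestamp,
    )
    (out_dir / "report.json").write_text(json.dumps(doc.to_dict(), indent=1, sort_keys=True))
    seg_rows = "\n".join(
        f"<tr><td>{r['segment']}</td><td>{r['percent']:.1f}</td>"
        f"<td>{r['scar_px']}</td><td>{r['total_px']}</td></tr>"
        for r in extents.to_rows()
    )
    html = _HTML_TEMPLATE.format(
        patient_id=meta.get("id", "anonymous"),
        study_date=meta.get("study_date", ""),
        created=timestamp,
        myo_ml=metrics.myocardial_volume_ml,
        scar_ml=metrics.scar_volume_ml,
        scar_g=metrics.scar_mass_g,
        extent=metrics.scar_extent_percent,
        mean_t=metrics.mean_transmurality,
        max_t=metrics.max_transmurality,
        segment_rows=seg_rows,
        bullseye16=base64.b64encode(png16).decode("ascii"),
        bullseye_chords=base64.b64encode(png_ch).decode("ascii"),
        provenance=json.dumps(provenance, indent=1, sort_keys=True),
    )
    (out_dir / "report.html").write_text(html)
    return doc
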