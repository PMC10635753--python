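"""Choropleth export and run provenance.

Joins a per-area posterior summary onto the area GeoJSON (adding median_rr,
ci_low, ci_high, significance and risk_band as feature properties), renders a
categorical choropleth of the three risk bands with an optional LISA cluster
overlay, and records run provenance (seed, config hash, package version) in a
JSON manifest alongside the outputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .geography import AreaUnit, write_areas_geojson

__all__ = ["join_summary_geojson", "render_choropleth", "write_manifest",
           "config_hash"]

_BAND_COLORS = {
    "at_or_below_average": "#ffffcc",
    "above_average_within_100pct": "#fd8d3c",
    "above_100pct": "#bd0026",
}
_LISA_EDGE = {
    "high_high": "#d7191c",
    "low_low": "#2c7bb6",
    "low_high": "#abd9e9",
    "high_low": "#fdae61",
}


def join_summary_geojson(
    areas: list[AreaUnit],
    summary: pd.DataFrame,
    path,
    lisa: pd.DataFrame | None = None,
) -> None:
    """Write area GeoJSON with the posterior summary (and optional LISA
    labels) attached as per-feature properties."""
    extra: dict[str, dict] = {}
    for row in summary.itertuples(index=False):
        extra[row.area_id] = {
            "median_rr": float(row.median_rr),
            "ci_low": float(row.ci_low),
            "ci_high": float(row.ci_high),
            "significance": row.significance,
            "risk_band": row.risk_band,
        }
    if lisa is not None:
        for row in lisa.itertuples(index=False):
            extra.setdefault(row.area_id, {})["lisa_label"] = row.label
    missing = [a.area_id for a in areas if a.area_id not in extra]
    if missing:
        raise ValueError(f"summary lacks areas: {missing}")
    write_areas_geojson(areas, path, extra_properties=extra)


def render_choropleth(
    areas: list[AreaUnit],
    summary: pd.DataFrame,
    path,
    lisa: pd.DataFrame | None = None,
    title: str = "Median smoothed relative risk",
) -> None:
    """Categorical choropleth of the three risk bands; LISA cluster labels,
    when given, are drawn as coloured outlines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection
    from matplotlib.patches import Patch

    band = dict(zip(summary["area_id"], summary["risk_band"]))
    lisa_label = (
        dict(zip(lisa["area_id"], lisa["label"])) if lisa is not None else {}
    )
    verts, face, edge, lw = [], [], [], []
    for a in areas:
        polys = getattr(a.geometry, "geoms", [a.geometry])
        for poly in polys:
            verts.append(np.asarray(poly.exterior.coords))
            face.append(_BAND_COLORS.get(band.get(a.area_id), "#dddddd"))
            lab = lisa_label.get(a.area_id, "not_significant")
            edge.append(_LISA_EDGE.get(lab, "#555555"))
            lw.append(2.0 if lab in _LISA_EDGE else 0.3)

    fig, ax = plt.subplots(figsize=(7, 7))
    ax.add_collection(
        PolyCollection(verts, facecolors=face, edgecolors=edge, linewidths=lw)
    )
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_title(title)
    handles = [Patch(facecolor=c, label=b.replace("_", " "))
               for b, c in _BAND_COLORS.items()]
    if lisa is not None:
        handles += [Patch(facecolor="white", edgecolor=c,
                          label=f"LISA {k.replace('_', '-')}")
                    for k, c in _LISA_EDGE.items()]
    ax.legend(handles=handles, loc="upper left", fontsize=7,
              bbox_to_anchor=(1.01, 1.0))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(out_dir, stage: str, seed, config: dict,
                   outputs: list[str]) -> str:
    """Record which seed and configuration produced each output file."""
    from pathlib import Path

    path = Path(out_dir) / f"{stage}_manifest.json"
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": {k: str(v) for k, v in config.items()},
        "outputs": [str(p) for p in outputs],
        "software_version": __version__,
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return str(path)
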