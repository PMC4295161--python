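"""Output writing and frame rendering.

CSV outputs use comma separators, UTF-8 and Unix newlines with no index
column.  Every file set is stamped with a configuration hash in
``meta.json`` so that downstream analysis can detect mismatched inputs.
Frames are PNG images, one per simulated hour, with the ten germ-cell
types colour-coded and co-occupied spermatid compartments drawn split.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .environment import EPITHELIUM, LUMEN, OUTSIDE, SERTOLI
from .parameters import (CELL_TYPES, ELONGATED_SPTD, ParameterSet,
                         SPERMATID_TYPES, TYPE_ORDER, params_to_flat)
from .simulation import SimulationResult, SimulationState

__all__ = ["FrameSpec", "write_counts", "read_counts", "write_events",
           "write_radial", "write_lineage", "write_meta", "save_result",
           "config_hash", "render_frame", "frame_filename"]


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------


def config_hash(params: ParameterSet) -> str:
    flat = params_to_flat(params)
    blob = json.dumps(flat, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_counts(result: SimulationResult, path) -> None:
    """Hourly per-type counts plus per-hour and cumulative sperm; one row
    per simulated hour, lossless on round-trip."""
    result.counts_frame().to_csv(path, index=False, lineterminator="\n")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(result: SimulationResult, path) -> None:
    df = pd.DataFrame(result.events, columns=[
        "time", "event", "cell_id", "lineage_id", "type_before",
        "type_after", "pos_index"])
    df.to_csv(path, index=False, lineterminator="\n")


def write_radial(result: SimulationResult, path) -> None:
    from .analytics import radial_profile
    radial_profile(result).to_csv(path, index=False, lineterminator="\n",
                                  float_format="%.4f")


def write_lineage(result: SimulationResult, path) -> None:
    """Per-cell lineage records: birth, final type and fate."""
    records: dict[str, list] = {}
    for t, event, cid, lid, before, after, _idx in result.events:
        rec = records.setdefault(lid, [None, before, "alive", None, cid])
        rec[4] = cid
        if event == "divide":
            if before in ("diplotene", "secondary"):
                rec[2], rec[3] = "divided", t
                for child in after.split("+"):
                    records.setdefault(child, [t, "", "alive", None, None])
            else:
                records.setdefault(after, [t, "diff_spg", "alive", None, None])
        elif event == "differentiate":
            rec[1] = after
        elif event == "die":
            rec[2], rec[3] = "died", t
        elif event == "release":
            rec[2], rec[3] = "sperm", t
    rows = [(lid, *rec[:4]) for lid, rec in sorted(records.items())]
    pd.DataFrame(rows, columns=["lineage_id", "birth_time", "last_type",
                                "fate", "fate_time"]).to_csv(
        path, index=False, lineterminator="\n")


def write_meta(result: SimulationResult, path) -> None:
    meta = {
        "version": 1,
        "seed": result.seed,
        "hours": result.hours,
        "scenario": result.scenario_name,
        "config_hash": config_hash(result.params),
        "params": params_to_flat(result.params),
        "anchors": list(map(int, result.anchors)),
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def save_result(result: SimulationResult, out_dir) -> None:
    """Write the standard file set: counts, events, lineage, radial, meta."""
    os.makedirs(out_dir, exist_ok=True)
    write_counts(result, os.path.join(out_dir, "counts.csv"))
    write_events(result, os.path.join(out_dir, "events.csv"))
    write_lineage(result, os.path.join(out_dir, "lineage.csv"))
    write_radial(result, os.path.join(out_dir, "radial.csv"))
    write_meta(result, os.path.join(out_dir, "meta.json"))


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

DEFAULT_COLORS = {
    "stem": (178, 24, 43),
    "diff_spg": (239, 138, 98),
    "preleptotene": (253, 219, 199),
    "leptotene": (255, 255, 51),
    "zygotene": (166, 217, 106),
    "pachytene": (26, 152, 80),
    "diplotene": (0, 136, 136),
    "secondary": (33, 102, 172),
    "round_sptd": (146, 112, 219),
    "elongated_sptd": (118, 42, 131),
}


@dataclass
class FrameSpec:
    """Rendering style: per-type colours (all ten distinct), region
    colours and the pixel scale of one micro-compartment."""

    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    lumen_color: tuple = (25, 25, 112)
    epithelium_color: tuple = (173, 216, 230)
    sertoli_color: tuple = (128, 128, 128)
    interstitial_color: tuple = (200, 30, 30)
    outside_color: tuple = (255, 255, 255)
    scale: int = 8
    legend: bool = True


def _agent_glyphs(state: SimulationState) -> list[tuple[int, str, int]]:
    """(position index, cell type, slot) of every drawable agent; slot
    0/1 splits co-occupied spermatid compartments."""
    glyphs = []
    slot_used: dict[int, int] = {}
    for a in state.agents.values():
        slot = slot_used.get(a.idx, 0)
        slot_used[a.idx] = slot + 1
        glyphs.append((a.idx, a.cell_type, slot))
    return glyphs


def frame_filename(hour: int) -> str:
    return f"frame_{hour:06d}.png"


def render_frame(state: SimulationState, spec: FrameSpec | None = None) -> Image.Image:
    """Render the current state to a PNG-ready image.

    The grid occupies ``(2 * tubule_radius + 1) * scale`` pixels per side;
    a legend strip is appended below unless disabled.
    """
    spec = spec or FrameSpec()
    g = state.grid
    W, s = g.width, spec.scale
    legend_h = (14 * s if spec.legend else 0)
    img = Image.new("RGB", (W * s, W * s + legend_h), spec.outside_color)
    draw = ImageDraw.Draw(img)
    region_color = {OUTSIDE: spec.outside_color, LUMEN: spec.lumen_color,
                    EPITHELIUM: spec.epithelium_color,
                    SERTOLI: spec.sertoli_color}
    for i in range(W * W):
        col, row = i % W, i // W
        draw.rectangle([col * s, row * s, (col + 1) * s - 1, (row + 1) * s - 1],
                       fill=region_color[g.region[i]])
    for i in g.marker_idx:
        col, row = i % W, i // W
        draw.rectangle([col * s, row * s, (col + 1) * s - 1, (row + 1) * s - 1],
                       outline=spec.interstitial_color, width=max(1, s // 4))
    for idx, cell_type, slot in _agent_glyphs(state):
        col, row = idx % W, idx // W
        x0, y0 = col * s, row * s
        color = spec.colors[cell_type]
        if cell_type in SPERMATID_TYPES:
            # split compartment: left/right half-cells
            half = s // 2
            x0 = x0 + slot * half
            if cell_type == ELONGATED_SPTD:
                draw.rectangle([x0 + 1, y0 + 1, x0 + max(half - 2, 1),
                                y0 + s - 2], fill=color)
            else:
                draw.ellipse([x0, y0 + s // 4, x0 + half - 1,
                              y0 + s - s // 4], fill=color)
        else:
            d = CELL_TYPES[cell_type].diameter_um / 13.0  # fraction of cell
            pad = max(int(s * (1 - d) / 2), 0)
            draw.ellipse([x0 + pad, y0 + pad, x0 + s - 1 - pad,
                          y0 + s - 1 - pad], fill=color)
    if spec.legend:
        y = W * s + 2
        x = 2
        for t in TYPE_ORDER:
            draw.rectangle([x, y, x + s - 1, y + s - 1], fill=spec.colors[t])
            draw.text((x + s + 2, y), t, fill=(0, 0, 0))
            y += s + 2
            if y > W * s + legend_h - s:
                y = W * s + 2
                x += 11 * s
    return img
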