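"""Vest electrode geometry.

The 252-lead mapping vest is modelled as two rectangular electrode grids
(anterior and posterior torso panels) unrolled side by side in a 2-D plane.
Exact manufacturer coordinates are proprietary, so the default geometry is a
synthetic but consistent layout: a 9 x 14 grid per panel (126 + 126 = 252
leads), with the posterior panel offset along x.  Lead indices are 0-based
internally; files and reports use 1-based vest labels.

Standard-ECG analogue subsets are defined positionally: ``ecg8_leads``
approximates the six precordial electrodes (mid-height anterior row) plus two
limb-equivalent electrodes (lower anterior corners); ``ecg11_leads`` adds
three posterior electrodes (V8/V9/V10 analogues) on the same horizontal plane
as V6.  Both are configuration, not a claim about the clinical vest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, FormatError

__all__ = ["VestGeometry", "default_geometry", "grid_geometry"]


@dataclass(frozen=True)
class VestGeometry:
    """Electrode count, planar positions and ECG-analogue subsets."""

    n_leads: int
    positions: np.ndarray  # (n_leads, 2) float
    ecg8_leads: tuple[int, ...]
    ecg11_leads: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if self.n_leads < 1:
            raise ConfigError("n_leads must be a positive integer")
        if pos.shape != (self.n_leads, 2):
            raise ConfigError(
                f"positions must have shape ({self.n_leads}, 2), got {pos.shape}"
            )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ecg8_leads", tuple(int(i) for i in self.ecg8_leads))
        object.__setattr__(self, "ecg11_leads", tuple(int(i) for i in self.ecg11_leads))
        for name, leads, size in (
            ("ecg8_leads", self.ecg8_leads, 8),
            ("ecg11_leads", self.ecg11_leads, 11),
        ):
            if len(leads) != size:
                raise ConfigError(f"{name} must contain {size} leads, got {len(leads)}")
            if len(set(leads)) != len(leads):
                raise ConfigError(f"{name} contains duplicate lead indices")
            if any(i < 0 or i >= self.n_leads for i in leads):
                raise ConfigError(f"{name} contains out-of-range lead indices")
        if not set(self.ecg8_leads) <= set(self.ecg11_leads):
            raise ConfigError("ecg8_leads must be a subset of ecg11_leads")

    # ------------------------------------------------------------------ io
    def to_json(self, path: str | Path) -> None:
        """Write the geometry as JSON (lead labels 1-based in the file)."""
        doc = {
            "n_leads": self.n_leads,
            "positions": self.positions.tolist(),
            "ecg8": [i + 1 for i in self.ecg8_leads],
            "ecg11": [i + 1 for i in self.ecg11_leads],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "VestGeometry":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"geometry file {path} is not valid JSON: {exc}") from exc
        for key in ("n_leads", "positions", "ecg8", "ecg11"):
            if key not in doc:
                raise FormatError(f"geometry file {path} is missing field '{key}'")
        return cls(
            n_leads=int(doc["n_leads"]),
            positions=np.asarray(doc["positions"], dtype=float),
            ecg8_leads=tuple(int(i) - 1 for i in doc["ecg8"]),
            ecg11_leads=tuple(int(i) - 1 for i in doc["ecg11"]),
        )

    @classmethod
    def for_n_leads(cls, n_leads: int) -> "VestGeometry":
        """Best-effort geometry for an arbitrary even lead count.

        Splits ``n_leads`` into two panels of rows x cols with aspect ratio as
        close as possible to the default 9:14 panel.
        """
        if n_leads == 252:
            return default_geometry()
        if n_leads % 2:
            raise ConfigError(
                f"cannot infer a two-panel geometry for odd lead count {n_leads}; "
                "provide an explicit VestGeometry"
            )
        per_panel = n_leads // 2
        best = None
        for rows in range(3, per_panel + 1):
            if per_panel % rows:
                continue
            cols = per_panel // rows
            if cols < 6:
                continue
            score = abs(rows / cols - 9 / 14)
            if best is None or score < best[0]:
                best = (score, rows, cols)
        if best is None:
            raise ConfigError(
                f"no admissible two-panel grid for {n_leads} leads (need >=3 rows, >=6 cols)"
            )
        return grid_geometry(best[1], best[2])


def _panel_positions(rows: int, cols: int, x0: float) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(cols, dtype=float) + x0, np.arange(rows, dtype=float))
    return np.column_stack([xs.ravel(), ys.ravel()])


def grid_geometry(rows: int, cols: int) -> VestGeometry:
    """Two rows x cols panels; lead index = panel*rows*cols + row*cols + col."""
    if rows < 3 or cols < 6:
        raise ConfigError("grid geometry needs rows >= 3 and cols >= 6")
    per_panel = rows * cols
    anterior = _panel_positions(rows, cols, 0.0)
    posterior = _panel_positions(rows, cols, cols + 1.0)  # unrolled, gap of 1
    positions = np.vstack([anterior, posterior])

    mid = rows // 2
    precordial_cols = np.unique(np.round(np.linspace(0, cols - 1, 6)).astype(int))
    assert len(precordial_cols) == 6
    precordial = [mid * cols + c for c in precordial_cols]
    limb = [(rows - 1) * cols + 0, (rows - 1) * cols + (cols - 1)]
    ecg8 = tuple(precordial + limb)
    post_cols = np.unique(np.round(np.linspace(0, cols - 1, 3)).astype(int))
    posterior3 = [per_panel + mid * cols + c for c in post_cols]
    ecg11 = tuple(list(ecg8) + posterior3)
    return VestGeometry(2 * per_panel, positions, ecg8, ecg11)


def default_geometry() -> VestGeometry:
    """The canonical 252-lead two-panel geometry (9 x 14 per panel)."""
    return grid_geometry(9, 14)
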