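"""Reader and writer for TPS landmark files (tpsDig dialect).

The dialect handled here is the one produced by tpsDig-style digitising
tools: each record starts with ``LM=<k>``, followed by ``k`` whitespace
separated coordinate rows, then optional ``IMAGE=``, ``ID=`` and ``SCALE=``
lines.  ``SCALE`` is the physical size of one image unit (e.g. mm per
pixel); on read it is multiplied into the coordinates by default, which is
how digitised images carrying a reference scale are calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["TPSRecord", "TPSFormatError", "read_tps", "write_tps"]


class TPSFormatError(ValueError):
    """Raised when a TPS file does not follow the expected dialect."""


@dataclass
class TPSRecord:
    """One landmark configuration as stored in a TPS file."""

    coords: np.ndarray  # k x 2, scale already applied if requested on read
    id: str = ""
    image: str = ""
    scale: float | None = None
    raw_coords: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise TPSFormatError("coordinates must form a k x 2 matrix")
        if not np.isfinite(self.coords).all():
            raise TPSFormatError("non-finite coordinate")


def write_tps(records: Sequence[TPSRecord], path: str | Path) -> None:
    """Write records to ``path``; rejects mixed landmark counts.

    Coordinates are written with full double precision (``repr`` round-trip
    format), so ``read_tps(write_tps(x))`` is bit-exact.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    ks = {len(r.coords) for r in records}
    if len(ks) != 1:
        raise TPSFormatError(f"mixed landmark counts {sorted(ks)}; TPS datasets must share k")
    lines: list[str] = []
    for rec in records:
        coords = rec.raw_coords if rec.raw_coords is not None else rec.coords
        coords = np.asarray(coords, dtype=float)
        lines.append(f"LM={len(coords)}")
        for x, y in coords:
            lines.append(f"{float(x)!r} {float(y)!r}")
        if rec.image:
            lines.append(f"IMAGE={rec.image}")
        if rec.id:
            lines.append(f"ID={rec.id}")
        if rec.scale is not None:
            lines.append(f"SCALE={float(rec.scale)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path: str | Path, apply_scale: bool = True) -> list[TPSRecord]:
    """Parse a TPS file into records.

    With ``apply_scale`` (default) coordinates are multiplied by the SCALE
    factor when one is present; the unscaled values are kept in
    ``raw_coords``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[TPSRecord] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise TPSFormatError(f"{path}:{i}: expected 'LM=' record header, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSFormatError(f"{path}:{i}: malformed landmark count in {line!r}") from exc
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= n:
                raise TPSFormatError(f"{path}:{i}: file ends inside a record (expected {k} rows)")
            row = lines[i].strip()
            i += 1
            parts = row.split()
            if len(parts) != 2 or "=" in row:
                raise TPSFormatError(
                    f"{path}:{i}: expected coordinate row {j + 1}/{k}, got {row!r} "
                    f"(LM={k} does not match the rows present)"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TPSFormatError(f"{path}:{i}: non-numeric coordinate {row!r}") from exc
        rec_id = ""
        image = ""
        scale: float | None = None
        while i < n:
            peek = lines[i].strip()
            if not peek:
                i += 1
                continue
            upper = peek.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("IMAGE="):
                image = peek.split("=", 1)[1]
            elif upper.startswith("ID="):
                rec_id = peek.split("=", 1)[1]
            elif upper.startswith("SCALE="):
                try:
                    scale = float(peek.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSFormatError(f"{path}:{i + 1}: malformed SCALE line {peek!r}") from exc
            else:
                raise TPSFormatError(f"{path}:{i + 1}: unrecognised line {peek!r}")
            i += 1
        raw = coords
        if apply_scale and scale is not None:
            coords = coords * scale
        records.append(TPSRecord(coords=coords, id=rec_id, image=image, scale=scale, raw_coords=raw))
    if not records:
        raise TPSFormatError(f"{path}: no records found")
    return records
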