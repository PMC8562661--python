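"""Text stream dialect for simulated reflection lists.

Self-defined, versioned, loosely inspired by serial-crystallography stream
files but bit-exact on round trip. Layout::

    PINKSFX STREAM 1
    key = value          (header: cell, symmetry, spectrum, sim config)
    BEGIN PATTERN <idx>
    orientation <9 floats row-major>
    spectrum <id>
    scale <float>
    <n_spots> rows: h k l I sigma partiality lambda x y
    END PATTERN

Floats are written with repr-exact precision (%.17g).
"""

from __future__ import annotations

import logging

import numpy as np

from . import geometry
from .errors import StreamParseError
from .simulate import Dataset, Pattern, SimConfig

log = logging.getLogger(__name__)

VERSION = 1
MAGIC = "PINKSFX STREAM"


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_stream(dataset: Dataset, path) -> None:
    cell = dataset.cell
    cfg = dataset.config
    with open(path, "w") as fh:
        fh.write(f"{MAGIC} {VERSION}\n")
        for key, val in (
            ("cell", " ".join(_fmt(v) for v in (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma))),
            ("space_group", dataset.symmetry),
            ("spectrum", dataset.spectrum_id),
            ("d_min", _fmt(dataset.d_min)),
            ("n_patterns", str(dataset.n_patterns)),
            ("fluence_scale", _fmt(cfg.fluence_scale)),
            ("background_counts", _fmt(cfg.background_counts)),
            ("scale_jitter_sd", _fmt(cfg.scale_jitter_sd)),
            ("seed", str(cfg.seed)),
            ("fingerprint", dataset.fingerprint or "-"),
        ):
            fh.write(f"{key} = {val}\n")
        for p in dataset.patterns:
            fh.write(f"BEGIN PATTERN {p.index}\n")
            fh.write("orientation " + " ".join(_fmt(v) for v in p.rotation.ravel()) + "\n")
            fh.write(f"spectrum {p.spectrum_id}\n")
            fh.write(f"scale {_fmt(p.scale)}\n")
            fh.write(f"{p.n_spots}\n")
            for i in range(p.n_spots):
                fh.write(
                    f"{p.miller[i, 0]} {p.miller[i, 1]} {p.miller[i, 2]} "
                    f"{_fmt(p.intensity[i])} {_fmt(p.sigma[i])} {_fmt(p.partiality[i])} "
                    f"{_fmt(p.lam[i])} {_fmt(p.x[i])} {_fmt(p.y[i])}\n"
                )
            fh.write("END PATTERN\n")


class _Lines:
    """Line reader that tracks numbers for error messages."""

    def __init__(self, fh):
        self.fh = fh
        self.n = 0

    def next(self) -> str:
        line = self.fh.readline()
        if not line:
            raise StreamParseError(f"line {self.n + 1}: unexpected end of file")
        self.n += 1
        return line.rstrip("\n")

    def error(self, msg: str) -> StreamParseError:
        return StreamParseError(f"line {self.n}: {msg}")


def read_stream(path) -> Dataset:
    """Parse a stream file back into a Dataset (lossless round trip).

    An empty file yields an empty dataset with a warning. Malformed content
    raises StreamParseError naming the offending line.
    """
    with open(path) as fh:
        lines = _Lines(fh)
        first = fh.readline()
        if not first:
            log.warning("empty stream file %s", path)
            return Dataset(
                patterns=[],
                cell=geometry.UnitCell(1, 1, 1),
                symmetry="P1",
                spectrum_id="",
                d_min=1.0,
                config=SimConfig(n_patterns=1),
            )
        lines.n = 1
        parts = first.split()
        if parts[:2] != MAGIC.split() or len(parts) != 3:
            raise lines.error(f"not a {MAGIC} file")
        if int(parts[2]) != VERSION:
            raise lines.error(f"unsupported stream version {parts[2]}")
        header = {}
        line = lines.next()
        while "=" in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
            line = lines.next()
        try:
            cv = [float(x) for x in header["cell"].split()]
            cell = geometry.UnitCell(*cv)
            cfg = SimConfig(
                n_patterns=max(1, int(header["n_patterns"])),
                fluence_scale=float(header["fluence_scale"]),
                background_counts=float(header["background_counts"]),
                scale_jitter_sd=float(header["scale_jitter_sd"]),
                seed=int(header["seed"]),
            )
        except (KeyError, ValueError) as exc:
            raise lines.error(f"bad header: {exc}") from exc
        sym = geometry.SymmetrySpec.from_symbol(header["space_group"])

        patterns = []
        while True:
            if not line.startswith("BEGIN PATTERN"):
                raise lines.error(f"expected BEGIN PATTERN, got {line!r}")
            try:
                index = int(line.split()[2])
            except (IndexError, ValueError):
                raise lines.error("malformed BEGIN PATTERN") from None
            rot_line = lines.next().split()
            if rot_line[0] != "orientation" or len(rot_line) != 10:
                raise lines.error("expected 'orientation' with 9 floats")
            rotation = np.array([float(v) for v in rot_line[1:]]).reshape(3, 3)
            spec_line = lines.next().split(maxsplit=1)
            if spec_line[0] != "spectrum" or len(spec_line) != 2:
                raise lines.error("expected 'spectrum <id>'")
            spectrum_id = spec_line[1]
            scale_line = lines.next().split()
            if scale_line[0] != "scale" or len(scale_line) != 2:
                raise lines.error("expected 'scale <float>'")
            scale = float(scale_line[1])
            try:
                n_spots = int(lines.next())
            except ValueError:
                raise lines.error("expected spot count") from None
            rows = np.empty((n_spots, 9))
            for i in range(n_spots):
                fields = lines.next().split()
                if len(fields) != 9:
                    raise lines.error(f"expected 9 fields, got {len(fields)}")
                try:
                    rows[i] = [float(v) for v in fields]
                except ValueError as exc:
                    raise lines.error(f"non-numeric field: {exc}") from None
            end = lines.next()
            if end != "END PATTERN":
                raise lines.error(f"expected END PATTERN, got {end!r}")
            miller = rows[:, :3].astype(int)
            if len(miller):
                canonical, minus, _ = geometry._asu_arrays(miller, sym)
            else:
                canonical = miller.copy()
                minus = np.zeros(0, bool)
            patterns.append(
                Pattern(
                    index=index,
                    rotation=rotation,
                    spectrum_id=spectrum_id,
                    scale=scale,
                    miller=miller,
                    asu=canonical,
                    friedel_minus=minus,
                    intensity=rows[:, 3],
                    sigma=rows[:, 4],
                    partiality=rows[:, 5],
                    lam=rows[:, 6],
                    x=rows[:, 7],
                    y=rows[:, 8],
                )
            )
            nxt = fh.readline()
            if not nxt:
                break
            lines.n += 1
            line = nxt.rstrip("\n")
    return Dataset(
        patterns=patterns,
        cell=cell,
        symmetry=sym.space_group_symbol,
        spectrum_id=header.get("spectrum", ""),
        d_min=float(header.get("d_min", "1")),
        config=cfg,
        fingerprint="" if header.get("fingerprint") in (None, "-") else header["fingerprint"],
    )
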