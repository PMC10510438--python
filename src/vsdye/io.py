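"""Plain-text interchange formats.

Per-frame series travel as tab-separated files with a commented key/value
header (kind, label, units, optionally state / v_mp / seed) followed by a
column-header line and the data rows. 3-D potential maps travel as OpenDX
scalar fields (regular orthogonal grids only), values in mV. Both formats
round-trip losslessly at full float precision (repr-level, 17 significant
digits).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .core import State, VoltageCondition
from .observables import AtomTrack, OrientationSeries
from .potential import PotentialGrid
from .spectral import EnergyGapSeries


class FormatError(ValueError):
    """A file violates the series/grid format contract."""


# ---------------------------------------------------------------------------
# columnar series
# ---------------------------------------------------------------------------

def _write_series(path, kind: str, columns: list[str],
                  rows: np.ndarray, meta: dict) -> None:
    lines = [f"# vsdye {kind}"]
    for key, val in meta.items():
        if val is not None:
            lines.append(f"# {key}: {val}")
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(_fmt(v, c) for v, c in zip(row, columns)))
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(v, col: str) -> str:
    return str(int(v)) if col == "frame" else repr(float(v))


def _read_series(path) -> tuple[str, dict, list[str], np.ndarray]:
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    kind = ""
    header: list[str] | None = None
    data_rows: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("vsdye "):
                kind = body.split(None, 1)[1]
            elif ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
            continue
        if header is None:
            if any(_is_number(tok) for tok in line.split("\t")):
                raise FormatError(
                    f"{path}: missing column-header line before data (line {lineno})"
                )
            header = line.split("\t")
            continue
        toks = line.split("\t")
        if len(toks) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(toks)}"
            )
        try:
            data_rows.append([float(t) for t in toks])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric value in data row: {line!r}"
            ) from None
    if not kind:
        raise FormatError(f"{path}: missing '# vsdye <kind>' header line")
    if header is None:
        raise FormatError(f"{path}: missing column-header line")
    if not data_rows:
        raise FormatError(f"{path}: no frames in data section")
    arr = np.asarray(data_rows, float)
    frames = arr[:, 0].astype(np.int64)
    if np.any(frames != arr[:, 0]):
        raise FormatError(f"{path}: frame indices must be integers")
    if len(frames) > 1 and not np.all(np.diff(frames) > 0):
        raise FormatError(
            f"{path}: frame indices must be strictly increasing "
            "(duplicate or shuffled rows)"
        )
    return kind, meta, header, arr


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _cond_meta(meta: dict, path) -> VoltageCondition | None:
    if "state" in meta and "v_mp" in meta:
        try:
            return VoltageCondition(v_mp=float(meta["v_mp"]),
                                    state=State(meta["state"]))
        except ValueError as exc:
            raise FormatError(f"{path}: bad condition metadata: {exc}") from exc
    return None


def write_track_tsv(path, track: AtomTrack, cond: VoltageCondition | None = None,
                    seed: int | None = None) -> None:
    meta = {"label": track.label, "units": "angstrom", "seed": seed}
    if cond is not None:
        meta |= {"state": cond.state.value, "v_mp": cond.v_mp}
    rows = np.column_stack((track.frames, track.z))
    _write_series(path, "atom_track", ["frame", "z"], rows, meta)


def read_track_tsv(path) -> AtomTrack:
    kind, meta, header, arr = _read_series(path)
    if kind != "atom_track":
        raise FormatError(f"{path}: expected an atom_track file, found {kind!r}")
    if "label" not in meta:
        raise FormatError(f"{path}: header lacks the atom label")
    return AtomTrack(label=meta["label"], frames=arr[:, 0], z=arr[:, 1])


def write_gap_tsv(path, series: EnergyGapSeries, seed: int | None = None) -> None:
    meta = {
        "units": "kcal/mol",
        "state": series.cond.state.value,
        "v_mp": series.cond.v_mp,
        "seed": seed,
    }
    rows = np.column_stack((series.frames, series.values))
    _write_series(path, "energy_gap", ["frame", "delta_e"], rows, meta)


def read_gap_tsv(path) -> EnergyGapSeries:
    kind, meta, header, arr = _read_series(path)
    if kind != "energy_gap":
        raise FormatError(f"{path}: expected an energy_gap file, found {kind!r}")
    cond = _cond_meta(meta, path)
    if cond is None:
        raise FormatError(f"{path}: header lacks state/v_mp condition metadata")
    return EnergyGapSeries(cond=cond, frames=arr[:, 0], values=arr[:, 1])


def write_orientation_tsv(path, orient: OrientationSeries,
                          cond: VoltageCondition | None = None,
                          seed: int | None = None) -> None:
    meta = {"units": "unit-vector", "seed": seed}
    if cond is not None:
        meta |= {"state": cond.state.value, "v_mp": cond.v_mp}
    rows = np.column_stack((orient.frames, orient.vectors))
    _write_series(path, "orientation", ["frame", "ux", "uy", "uz"], rows, meta)


def read_orientation_tsv(path) -> OrientationSeries:
    kind, meta, header, arr = _read_series(path)
    if kind != "orientation":
        raise FormatError(f"{path}: expected an orientation file, found {kind!r}")
    return OrientationSeries(frames=arr[:, 0], vectors=arr[:, 1:4])


# ---------------------------------------------------------------------------
# OpenDX scalar fields
# ---------------------------------------------------------------------------

def write_dx_grid(path, grid: PotentialGrid, comment: str = "") -> None:
    """Write a grid as an OpenDX regular scalar field (values in mV)."""
    nx, ny, nz = grid.shape
    out = _io.StringIO()
    out.write("# OpenDX scalar field written by vsdye; potential values in mV\n")
    for line in comment.splitlines():
        out.write(f"# {line}\n")
    out.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    out.write("origin {0!r} {1!r} {2!r}\n".format(*map(float, grid.origin)))
    out.write(f"delta {float(grid.spacing[0])!r} 0 0\n")
    out.write(f"delta 0 {float(grid.spacing[1])!r} 0\n")
    out.write(f"delta 0 0 {float(grid.spacing[2])!r}\n")
    out.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    out.write(
        f"object 3 class array type double rank 0 items {nx * ny * nz} "
        "data follows\n"
    )
    flat = grid.values.reshape(-1)  # C order: z fastest, x slowest
    for i in range(0, flat.size, 3):
        out.write(" ".join(repr(float(v)) for v in flat[i:i + 3]) + "\n")
    out.write('attribute "dep" string "positions"\n')
    out.write('object "regular positions regular connections" class field\n')
    out.write('component "positions" value 1\n')
    out.write('component "connections" value 2\n')
    out.write('component "data" value 3\n')
    Path(path).write_text(out.getvalue())


def read_dx_grid(path) -> PotentialGrid:
    """Read an OpenDX regular scalar field; rejects non-orthogonal deltas."""
    counts: list[int] | None = None
    origin: list[float] | None = None
    deltas: list[list[float]] = []
    n_items: int | None = None
    values: list[float] = []
    in_data = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if in_data:
            if toks[0] in ("attribute", "object", "component"):
                in_data = False
                continue
            try:
                values.extend(float(t) for t in toks)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value in data section"
                ) from None
            continue
        if toks[:4] == ["object", "1", "class", "gridpositions"]:
            counts = [int(t) for t in toks[-3:]]
        elif toks[0] == "origin":
            origin = [float(t) for t in toks[1:4]]
        elif toks[0] == "delta":
            deltas.append([float(t) for t in toks[1:4]])
        elif "data" in toks and "follows" in toks:
            idx = toks.index("items")
            n_items = int(toks[idx + 1])
            in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise FormatError(f"{path}: incomplete OpenDX header (counts/origin/deltas)")
    d = np.asarray(deltas, float)
    if not np.allclose(d, np.diag(np.diag(d)), atol=0.0):
        raise FormatError(f"{path}: non-orthogonal grid deltas are not supported")
    spacing = np.diag(d)
    n_expected = counts[0] * counts[1] * counts[2]
    if n_items is not None and n_items != n_expected:
        raise FormatError(
            f"{path}: header declares {n_items} items but counts imply {n_expected}"
        )
    if len(values) != n_expected:
        raise FormatError(
            f"{path}: data section has {len(values)} values, expected {n_expected}"
        )
    vals = np.asarray(values, float).reshape(counts)
    return PotentialGrid(origin=np.asarray(origin), spacing=spacing, values=vals)


# ---------------------------------------------------------------------------
# f(z) profiles
# ---------------------------------------------------------------------------

def write_profile_tsv(path, profile) -> None:
    rows = np.column_stack((profile.z, profile.f))
    lines = ["# vsdye potential_fraction", "# units: z angstrom, f dimensionless",
             "z\tf"]
    for z, f in rows:
        lines.append(f"{float(z)!r}\t{float(f)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_tsv(path):
    from .potential import PotentialFractionProfile

    z: list[float] = []
    f: list[float] = []
    saw_header = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not saw_header:
            saw_header = True
            continue
        toks = line.split("\t")
        if len(toks) != 2:
            raise FormatError(f"{path}:{lineno}: expected two columns")
        try:
            z.append(float(toks[0]))
            f.append(float(toks[1]))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric row") from None
    if not z:
        raise FormatError(f"{path}: no profile nodes")
    return PotentialFractionProfile(z=np.asarray(z), f=np.asarray(f))
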