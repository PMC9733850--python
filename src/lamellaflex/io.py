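"""Readers and writers for the package's on-disk formats.

Formats supported:

* GRO-dialect fixed-column coordinate files (nm on disk, Å in memory).
  The multilayer labelling travels in naming conventions: residue =
  lipid, residue name ``L000``… encodes the 0-based layer, bead names
  are ``H`` (head), ``T1``… (tail) and ``TE`` (terminal).  Parsing is
  delegated to MDAnalysis; labels are reconstructed from the names.
* Labeled XYZ — a self-describing text dialect with explicit per-bead
  lipid/layer/role columns.
* Two-column q–intensity scattering profiles with ``#`` comments.
* Topography as CSV grids (pixel size in a header comment) or 32-bit
  float TIFF (pixel size in the image description).
* Buckle tables as tab-separated ``lambda_nm  t_nm  strain``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BuckleObservation, LipidConfiguration, ScatteringProfile, TopographyMap
from .errors import FileFormatError

_ROLE_TO_NAME = {"head": "H", "terminal": "TE"}


def _bead_name(role: str, tail_counter: int) -> str:
    if role in _ROLE_TO_NAME:
        return _ROLE_TO_NAME[role]
    return f"T{tail_counter}"


def write_gro(config: LipidConfiguration, path: str | Path, title: str = "lamellaflex multilayer") -> None:
    """Write a configuration as a fixed-column GRO file (positions in nm)."""
    path = Path(path)
    lines = [title, f"{config.n_beads:5d}"]
    atom_no = 0
    prev_lipid = None
    tail_counter = 0
    for i in range(config.n_beads):
        lid = int(config.lipid_id[i])
        if lid != prev_lipid:
            tail_counter = 0
            prev_lipid = lid
        role = str(config.bead_role[i])
        if role == "tail":
            tail_counter += 1
        name = _bead_name(role, tail_counter)
        resname = f"L{int(config.layer_index[i]):03d}"
        atom_no += 1
        x, y, z = config.bead_positions[i] / 10.0  # A -> nm
        lines.append(
            f"{(lid + 1) % 100000:5d}{resname:<5s}{name:>5s}{atom_no % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    bx, by, bz = config.box / 10.0
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    path.write_text("\n".join(lines) + "\n")


def _precheck_gro(path: Path) -> None:
    """Cheap structural scan so malformed files fail with a line number."""
    text = path.read_text().splitlines()
    if len(text) < 3:
        raise FileFormatError(f"{path}: not a GRO file (needs title, count, box)")
    try:
        n_atoms = int(text[1].strip())
    except ValueError:
        raise FileFormatError(f"{path}: atom count is not an integer", line_number=2) from None
    if len(text) < n_atoms + 3:
        raise FileFormatError(
            f"{path}: expected {n_atoms} atom lines plus a box line", line_number=len(text)
        )
    for k in range(2, 2 + n_atoms):
        line = text[k]
        if len(line) < 44:
            raise FileFormatError(f"{path}: atom line too short", line_number=k + 1)
        for lo, hi in ((20, 28), (28, 36), (36, 44)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise FileFormatError(
                    f"{path}: malformed coordinate field '{line[lo:hi]}'", line_number=k + 1
                ) from None
    if not text[2 + n_atoms].split():
        raise FileFormatError(f"{path}: missing box line", line_number=3 + n_atoms)


def read_gro(path: str | Path) -> LipidConfiguration:
    """Read a GRO-dialect configuration written by :func:`write_gro`.

    Labels are reconstructed from the naming conventions; the result
    round-trips with the writer to the file's 0.001-nm precision.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _precheck_gro(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # pragma: no cover - precheck catches most
            raise FileFormatError(f"{path}: {exc}") from exc
    if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
        raise FileFormatError(f"{path}: missing or invalid box")

    positions = u.atoms.positions.astype(float)  # MDAnalysis: A
    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids

    roles = np.empty(len(names), dtype=object)
    layers = np.empty(len(names), dtype=int)
    for i, (name, resname) in enumerate(zip(names, resnames)):
        roles[i] = "head" if name == "H" else ("terminal" if name == "TE" else "tail")
        if not (resname.startswith("L") and resname[1:].isdigit()):
            raise FileFormatError(f"{path}: residue name {resname!r} does not encode a layer")
        layers[i] = int(resname[1:])

    # resids wrap at 100000; rebuild sequential lipid ids from changes
    lipid_id = np.zeros(len(resids), dtype=int)
    current = 0
    for i in range(1, len(resids)):
        if resids[i] != resids[i - 1]:
            current += 1
        lipid_id[i] = current

    config = LipidConfiguration(
        bead_positions=positions,
        lipid_id=lipid_id,
        layer_index=layers,
        bead_role=roles,
        box=u.dimensions[:3].astype(float),
    )
    config.validate_lipids()
    return config


def write_xyz(config: LipidConfiguration, path: str | Path) -> None:
    """Write a labeled-XYZ file: name x y z lipid_id layer role (Å)."""
    path = Path(path)
    lines = [str(config.n_beads), f'box="{config.box[0]:.6f} {config.box[1]:.6f} {config.box[2]:.6f}"']
    prev_lipid, tail_counter = None, 0
    for i in range(config.n_beads):
        lid = int(config.lipid_id[i])
        if lid != prev_lipid:
            tail_counter, prev_lipid = 0, lid
        role = str(config.bead_role[i])
        if role == "tail":
            tail_counter += 1
        name = _bead_name(role, tail_counter)
        x, y, z = config.bead_positions[i]
        lines.append(f"{name} {x:.6f} {y:.6f} {z:.6f} {lid} {int(config.layer_index[i])} {role}")
    path.write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> LipidConfiguration:
    """Read the labeled-XYZ dialect written by :func:`write_xyz`."""
    path = Path(path)
    text = path.read_text().splitlines()
    if len(text) < 2:
        raise FileFormatError(f"{path}: empty or truncated XYZ file")
    try:
        n = int(text[0].strip())
    except ValueError:
        raise FileFormatError(f"{path}: first line must be the bead count", line_number=1) from None
    comment = text[1]
    if 'box="' not in comment:
        raise FileFormatError(f"{path}: comment line must carry box=\"bx by bz\"", line_number=2)
    box = np.array([float(v) for v in comment.split('box="')[1].split('"')[0].split()])
    if len(text) < n + 2:
        raise FileFormatError(f"{path}: expected {n} bead lines", line_number=len(text))
    pos = np.empty((n, 3))
    lipid_id = np.empty(n, dtype=int)
    layer = np.empty(n, dtype=int)
    role = np.empty(n, dtype=object)
    for k in range(n):
        parts = text[k + 2].split()
        if len(parts) != 7:
            raise FileFormatError(f"{path}: expected 7 fields", line_number=k + 3)
        try:
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            lipid_id[k] = int(parts[4])
            layer[k] = int(parts[5])
        except ValueError:
            raise FileFormatError(f"{path}: malformed numeric field", line_number=k + 3) from None
        role[k] = parts[6]
    config = LipidConfiguration(
        bead_positions=pos, lipid_id=lipid_id, layer_index=layer, bead_role=role, box=box
    )
    config.validate_lipids()
    return config


def write_scattering_profile(profile: ScatteringProfile, path: str | Path) -> None:
    """Write q (Å⁻¹) and intensity as two whitespace-separated columns."""
    header = f"lamellaflex scattering profile: {profile.label}\ncolumns: q_invA intensity"
    np.savetxt(path, np.column_stack([profile.q, profile.intensity]), header=header)


def read_scattering_profile(path: str | Path, label: str | None = None) -> ScatteringProfile:
    """Read a two-column q–intensity text file (``#`` comments, whitespace or CSV)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    except Exception as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FileFormatError(f"{path}: expected two columns (q, intensity)")
    return ScatteringProfile(
        q=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        label=label if label is not None else path.stem,
    )


def write_topography_csv(topo: TopographyMap, path: str | Path) -> None:
    np.savetxt(path, topo.heights, delimiter=",", header=f"pixel_size_nm={topo.pixel_size}")


def read_topography_csv(path: str | Path, pixel_size: float | None = None) -> TopographyMap:
    """Read a CSV height grid; pixel size from the header comment or argument."""
    path = Path(path)
    if pixel_size is None:
        with open(path) as fh:
            first = fh.readline()
        if "pixel_size_nm=" in first:
            pixel_size = float(first.split("pixel_size_nm=")[1].split()[0])
        else:
            raise FileFormatError(f"{path}: no pixel_size_nm header; pass pixel_size explicitly")
    heights = np.loadtxt(path, delimiter=",")
    return TopographyMap(heights=heights, pixel_size=pixel_size)


def write_topography_tiff(topo: TopographyMap, path: str | Path) -> None:
    """Write heights as 32-bit float TIFF, pixel size in the description."""
    import tifffile

    tifffile.imwrite(
        path,
        topo.heights.astype(np.float32),
        description=json.dumps({"pixel_size_nm": topo.pixel_size}),
    )


def read_topography_tiff(path: str | Path, pixel_size: float | None = None) -> TopographyMap:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        heights = tif.asarray().astype(float)
        if pixel_size is None:
            desc = tif.pages[0].description or ""
            try:
                pixel_size = float(json.loads(desc)["pixel_size_nm"])
            except (ValueError, KeyError, json.JSONDecodeError):
                raise FileFormatError(
                    f"{path}: no pixel size in TIFF description; pass pixel_size explicitly"
                ) from None
    return TopographyMap(heights=heights, pixel_size=pixel_size)


def write_buckle_table(obs: list[BuckleObservation], path: str | Path) -> None:
    """Write buckle observations as tab-separated ``lambda_nm t_nm strain``."""
    df = pd.DataFrame(
        {"lambda_nm": [o.lam for o in obs], "t_nm": [o.t for o in obs], "strain": [o.eps for o in obs]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_buckle_table(path: str | Path) -> list[BuckleObservation]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    required = {"lambda_nm", "t_nm", "strain"}
    if not required.issubset(df.columns):
        raise FileFormatError(f"{path}: needs columns {sorted(required)}, got {list(df.columns)}")
    return [
        BuckleObservation(lam=row.lambda_nm, t=row.t_nm, eps=row.strain)
        for row in df.itertuples()
    ]
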