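"""Multi-model PDB reader/writer for trajectories.

MODEL/ENDMDL records delimit frames; each model must carry exactly one
ATOM record per topology atom, in topology order.  Coordinates are Å.
PDB serial numbers are presentation only — atom identity is positional.
"""

from __future__ import annotations

import numpy as np

from .topology import ConsistencyError, Topology, Trajectory


class PdbFormatError(ConsistencyError):
    pass


def write_multimodel_pdb(trajectory: Trajectory, path) -> None:
    top = trajectory.topology
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        coords = trajectory.coordinates[f]
        for a in top.atoms:
            res = top.residues[a.residue_index]
            x, y, z = coords[a.index]
            name = a.name[:4]
            # PDB columns: 4-char names start at col 13 unless 4 long
            name_field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {a.index + 1:5d} {name_field}"
                f" {res.name[:3]:>3s} A{a.residue_index + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_multimodel_pdb(path, topology: Topology,
                        frame_spacing_ps: float = 10.0) -> Trajectory:
    """Read a multi-model PDB into a trajectory over ``topology``.

    Frame times are synthesized on a uniform grid (default 10 ps, the
    trajectory-saving interval of the study) since PDB carries none.
    """
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] | None = None
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:  # single-model file without MODEL
                    current = []
                current.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
            elif rec == "ENDMDL":
                if current is None:
                    raise PdbFormatError("ENDMDL without MODEL")
                _check_frame(current, len(frames), topology)
                frames.append(np.array(current))
                current = None
    if current:
        _check_frame(current, len(frames), topology)
        frames.append(np.array(current))
    if not frames:
        raise PdbFormatError("no coordinate models found")
    coords = np.stack(frames)
    times = frame_spacing_ps * np.arange(len(frames))
    return Trajectory(coordinates=coords, frame_times=times, topology=topology)


def _check_frame(atoms, frame_index: int, topology: Topology) -> None:
    if len(atoms) != topology.n_atoms:
        raise PdbFormatError(
            f"frame {frame_index} has {len(atoms)} atoms, topology has "
            f"{topology.n_atoms}"
        )
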