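"""Trajectory, mesh and checkpoint I/O (XYZ text, legacy VTK, HDF5)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from mesocell.dpd_core.particles import ParticleSystem
from mesocell.membrane.mesh import TriMesh
from mesocell.cytoskeleton.network import FilamentNetwork
from mesocell.cell_assembly.config import TopologyStats
from mesocell.cell_assembly.generate import CellBundle

_TYPE_SYMBOLS = {1: "F", 2: "C", 3: "M", 4: "N", 5: "W"}
_SYMBOL_TYPES = {v: k for k, v in _TYPE_SYMBOLS.items()}


def write_xyz(path, positions: np.ndarray, types: np.ndarray, comment: str = "", mode: str = "w") -> None:
    with open(path, mode) as fh:
        fh.write(f"{positions.shape[0]}\n{comment}\n")
        for p, t in zip(positions, types):
            fh.write(
                f"{_TYPE_SYMBOLS.get(int(t), 'X')} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n"
            )


def read_xyz(path) -> list[tuple[np.ndarray, np.ndarray]]:
    """All frames of an (extended) XYZ file as (positions, types) tuples."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        body = lines[i + 2 : i + 2 + n]
        pos = np.array([[float(x) for x in l.split()[1:4]] for l in body])
        typ = np.array([_SYMBOL_TYPES.get(l.split()[0], 0) for l in body], np.int64)
        frames.append((pos, typ))
        i += 2 + n
    return frames


def write_vtk_mesh(path, mesh: TriMesh, positions: np.ndarray) -> None:
    """Legacy ASCII VTK polydata with triangle connectivity preserved."""
    faces = mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmesocell membrane\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {positions.shape[0]} float\n")
        for p in positions:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"POLYGONS {faces.shape[0]} {faces.shape[0] * 4}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_vtk_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    pts, faces = [], []
    i = 0
    while i < len(lines):
        if lines[i].startswith("POINTS"):
            n = int(lines[i].split()[1])
            for j in range(i + 1, i + 1 + n):
                pts.append([float(x) for x in lines[j].split()])
            i += n
        elif lines[i].startswith("POLYGONS"):
            n = int(lines[i].split()[1])
            for j in range(i + 1, i + 1 + n):
                faces.append([int(x) for x in lines[j].split()[1:]])
            i += n
        i += 1
    return np.asarray(pts), np.asarray(faces, np.int64)


def write_off_mesh(path, mesh: TriMesh, positions: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{positions.shape[0]} {mesh.faces.shape[0]} {mesh.edges.shape[0]}\n")
        for p in positions:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_off_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = [l for l in fh.read().splitlines() if l and not l.startswith("#")]
    assert lines[0].strip() == "OFF"
    nv, nf, _ = (int(x) for x in lines[1].split())
    pts = np.array([[float(x) for x in l.split()] for l in lines[2 : 2 + nv]])
    faces = np.array(
        [[int(x) for x in l.split()[1:4]] for l in lines[2 + nv : 2 + nv + nf]],
        np.int64,
    )
    return pts, faces


def write_hdf5_checkpoint(path, system: ParticleSystem, step: int = 0, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["step"] = step
        fh.attrs["mass"] = system.mass
        for k, v in (meta or {}).items():
            fh.attrs[k] = v
        # single-precision storage (forces are accumulated in double)
        fh.create_dataset("positions", data=system.positions.astype(np.float32))
        fh.create_dataset("velocities", data=system.velocities.astype(np.float32))
        fh.create_dataset("types", data=system.types)
        fh.create_dataset("box", data=system.box)
        fh.create_dataset("periodic", data=system.periodic.astype(np.int8))


def read_hdf5_checkpoint(path) -> tuple[ParticleSystem, int]:
    with h5py.File(path, "r") as fh:
        system = ParticleSystem(
            positions=fh["positions"][...].astype(np.float64),
            velocities=fh["velocities"][...].astype(np.float64),
            types=fh["types"][...],
            box=fh["box"][...],
            periodic=fh["periodic"][...].astype(bool),
            mass=float(fh.attrs["mass"]),
        )
        return system, int(fh.attrs["step"])


class TrajectoryWriter:
    """Writes frames every ``cadence`` steps in xyz, vtk or h5 format."""

    def __init__(self, path, cadence: int = 1000, fmt: str = "xyz"):
        if fmt not in ("xyz", "vtk", "h5"):
            raise ValueError(f"unknown trajectory format {fmt!r}")
        self.path = Path(path)
        self.cadence = cadence
        self.fmt = fmt
        self.n_written = 0

    def maybe_write(self, step: int, system: ParticleSystem, meshes=()) -> bool:
        if step % self.cadence != 0:
            return False
        self.write(step, system, meshes)
        return True

    def write(self, step: int, system: ParticleSystem, meshes=()) -> None:
        if self.fmt == "xyz":
            mode = "w" if self.n_written == 0 else "a"
            write_xyz(self.path, system.positions, system.types, f"step={step}", mode)
        elif self.fmt == "vtk":
            for k, mesh in enumerate(meshes):
                out = self.path.with_suffix(f".{step}.{k}.vtk")
                write_vtk_mesh(out, mesh, system.positions[mesh.vertex_slice])
            if not meshes:
                write_xyz(
                    self.path.with_suffix(f".{step}.xyz"),
                    system.positions,
                    system.types,
                    f"step={step}",
                )
        else:
            write_hdf5_checkpoint(self.path.with_suffix(f".{step}.h5"), system, step)
        self.n_written += 1


# ---------------------------------------------------------------------------
# cell bundles
# ---------------------------------------------------------------------------

def _mesh_doc(mesh: TriMesh | None) -> dict | None:
    if mesh is None:
        return None
    return {
        "faces": mesh.faces.tolist(),
        "edges": mesh.edges.tolist(),
        "edge_l0": mesh.edge_l0.tolist(),
        "edge_lmax": mesh.edge_lmax.tolist(),
        "face_a0": mesh.face_a0.tolist(),
        "dihedrals": mesh.dihedrals.tolist(),
        "dihedral_phi0": mesh.dihedral_phi0.tolist(),
        "area0": mesh.area0,
        "volume0": mesh.volume0,
        "persistence": mesh.persistence,
        "c1": mesh.c1,
        "kb": mesh.kb,
        "ka": mesh.ka,
        "kv": mesh.kv,
        "gamma_c": mesh.gamma_c,
        "kbt": mesh.kbt,
        "offset": mesh.offset,
        "l0": mesh.l0,
    }


def _mesh_from_doc(doc: dict | None) -> TriMesh | None:
    if doc is None:
        return None
    arrays = {
        k: np.asarray(doc[k])
        for k in ("edge_l0", "edge_lmax", "face_a0", "dihedral_phi0")
    }
    return TriMesh(
        faces=np.asarray(doc["faces"], np.int64),
        edges=np.asarray(doc["edges"], np.int64),
        dihedrals=np.asarray(doc["dihedrals"], np.int64),
        area0=doc["area0"],
        volume0=doc["volume0"],
        persistence=doc["persistence"],
        c1=doc["c1"],
        kb=doc["kb"],
        ka=doc["ka"],
        kv=doc["kv"],
        gamma_c=doc["gamma_c"],
        kbt=doc["kbt"],
        offset=doc["offset"],
        l0=doc["l0"],
        edge_l0=arrays["edge_l0"],
        edge_lmax=arrays["edge_lmax"],
        face_a0=arrays["face_a0"],
        dihedral_phi0=arrays["dihedral_phi0"],
    )


def save_bundle(bundle: CellBundle, path) -> None:
    doc = {
        "positions": bundle.positions.tolist(),
        "types": bundle.types.tolist(),
        "cell_mesh": _mesh_doc(bundle.cell_mesh),
        "nucleus_mesh": _mesh_doc(bundle.nucleus_mesh),
        "network": json.loads(bundle.network.to_json()),
        "stats": {
            "mean_cls_per_filament": bundle.stats.mean_cls_per_filament,
            "sd_cls_per_filament": bundle.stats.sd_cls_per_filament,
            "n_filaments": bundle.stats.n_filaments,
            "n_cl_bonds": bundle.stats.n_cl_bonds,
            "cell_linked_fraction": bundle.stats.cell_linked_fraction,
            "nucleus_linked_fraction": bundle.stats.nucleus_linked_fraction,
            "free_cl_trace": bundle.stats.free_cl_trace,
        },
        "diameter": bundle.diameter,
        "nc_ratio": bundle.nc_ratio,
        "seed": bundle.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_bundle(path) -> CellBundle:
    with open(path) as fh:
        doc = json.load(fh)
    return CellBundle(
        positions=np.asarray(doc["positions"]),
        types=np.asarray(doc["types"], np.int64),
        cell_mesh=_mesh_from_doc(doc["cell_mesh"]),
        nucleus_mesh=_mesh_from_doc(doc["nucleus_mesh"]),
        network=FilamentNetwork.from_json(json.dumps(doc["network"])),
        stats=TopologyStats(**doc["stats"]),
        diameter=doc["diameter"],
        nc_ratio=doc["nc_ratio"],
        seed=doc["seed"],
    )
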