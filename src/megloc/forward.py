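"""Forward model: spherical-conductor lead fields and the linear projection.

The measurement model is ``M = G J + E``: a q x p lead-field matrix G maps
the p dipolar moment amplitudes (A·m, oriented along the cortical normals)
to the q sensors (tesla).  G is computed analytically for a current dipole
in a homogeneous conducting sphere (Sarvas formula); for MEG the field
outside the sphere depends only on the sphere center, not on its radius or
conductivity.  Sensors are modeled as point magnetometers with an
orientation (radial by default, the standard simplification of radial
gradiometers for a spherical model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorArray",
    "LeadField",
    "radial_sensor_cap",
    "spherical_lead_field",
    "project",
    "read_leadfield",
    "write_leadfield",
]

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass
class SensorArray:
    """MEG sensor geometry: positions (mm), unit orientations, kind label."""

    positions: np.ndarray
    orientations: np.ndarray
    kind: str = "radial_magnetometer"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, float))
        norms = np.linalg.norm(self.orientations, axis=1, keepdims=True)
        self.orientations = self.orientations / norms

    @property
    def n_sensors(self) -> int:
        return len(self.positions)


@dataclass
class LeadField:
    """q x p gain matrix in T per (A·m) with a provenance record."""

    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.matrix.shape


def radial_sensor_cap(
    n_sensors: int = 100,
    radius_mm: float = 110.0,
    coverage: float = 0.72,
) -> SensorArray:
    """Helmet-like cap of radial magnetometers over the upper head.

    ``coverage`` is the fraction of the sphere's z-extent covered from the
    top down (0.72 reaches below the temporal lobes, like a whole-head
    helmet).  Deterministic (Fibonacci lattice restricted to the cap).
    """
    # sample the lattice on the full sphere, keep the top cap, rescale count
    n_full = int(np.ceil(n_sensors / coverage * 2)) * 2
    k = np.arange(n_full)
    phi = (1 + np.sqrt(5.0)) / 2
    z = 1 - (2 * k + 1) / n_full
    theta = 2 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    zmin = 1 - 2 * coverage
    cap = pts[pts[:, 2] >= zmin]
    cap = cap[:n_sensors]
    pos = cap * radius_mm
    return SensorArray(positions=pos, orientations=cap, kind="radial_magnetometer")


def _sarvas_field(
    r_sensor: np.ndarray, r_dip: np.ndarray, q_moment: np.ndarray
) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a conducting sphere.

    Positions relative to the sphere center, in meters; moment in A·m.
    Vectorized over sensors: ``r_sensor`` is (q, 3).
    """
    a = r_sensor - r_dip  # (q,3)
    na = np.linalg.norm(a, axis=1)
    nr = np.linalg.norm(r_sensor, axis=1)
    ra = np.einsum("ij,ij->i", r_sensor, a)
    r0r = r_sensor @ r_dip
    F = na * (nr * na + nr**2 - r0r)
    gradF = (
        (na**2 / nr + ra / na + 2 * na + 2 * nr)[:, None] * r_sensor
        - (na + 2 * nr + ra / na)[:, None] * r_dip
    )
    qxr0 = np.cross(q_moment, r_dip)  # (3,)
    num = F[:, None] * qxr0[None, :] - (r_sensor @ qxr0)[:, None] * gradF
    return MU0_OVER_4PI * num / (F**2)[:, None]


def spherical_lead_field(
    sensors: SensorArray,
    surface,
    sphere_center=(0.0, 0.0, 0.0),
    sphere_radius: float = 95.0,
) -> LeadField:
    """Lead field for normal-oriented unit dipoles in a conducting sphere.

    ``G[j, i]`` is the field sensed by sensor j (projection of B on the
    sensor orientation) from a 1 A·m dipole at vertex i oriented along its
    cortical normal.  Geometry in mm is converted to meters internally.

    Raises
    ------
    ValueError
        If any dipole lies outside the model sphere (lists the vertices),
        or any sensor lies inside it.
    """
    center = np.asarray(sphere_center, float)
    vpos = (surface.vertices - center) * 1e-3  # m, sphere-centered
    spos = (sensors.positions - center) * 1e-3
    radius_m = sphere_radius * 1e-3
    vr = np.linalg.norm(vpos, axis=1)
    bad = np.flatnonzero(vr >= radius_m)
    if bad.size:
        raise ValueError(
            f"{bad.size} dipole(s) outside the model sphere: {bad[:10].tolist()}..."
        )
    sr = np.linalg.norm(spos, axis=1)
    if np.any(sr <= radius_m):
        raise ValueError("sensors must lie strictly outside the model sphere")

    q = sensors.n_sensors
    p = len(vpos)
    G = np.empty((q, p))
    ori = sensors.orientations
    for i in range(p):
        B = _sarvas_field(spos, vpos[i], surface.normals[i])
        G[:, i] = np.einsum("ij,ij->i", B, ori)
    return LeadField(
        matrix=G,
        provenance={
            "model": "sarvas_sphere",
            "sphere_center_mm": center.tolist(),
            "sphere_radius_mm": sphere_radius,
            "units": "T_per_Am",
            "q": q,
            "p": p,
        },
    )


def project(G: LeadField, J: np.ndarray) -> np.ndarray:
    """Noiseless forward projection ``M0 = G @ J`` (exact matrix product)."""
    mat = G.matrix if isinstance(G, LeadField) else np.asarray(G)
    J = np.asarray(J, float)
    if J.shape[0] != mat.shape[1]:
        raise ValueError(
            f"source dimension mismatch: G is {mat.shape}, J has {J.shape[0]} rows"
        )
    return mat @ J


# ---------------------------------------------------------------------------
# I/O: TSV dialect and npz binary container
# ---------------------------------------------------------------------------

def write_leadfield(path: str, G: LeadField) -> None:
    """Write a lead field; ``.tsv`` uses the documented text dialect,
    anything else the binary container (npz with shape/units/provenance)."""
    if str(path).endswith(".tsv"):
        q, p = G.shape
        with open(path, "w") as fh:
            fh.write(f"# q={q} p={p} units=T_per_Am\n")
            for row in G.matrix:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    else:
        import json

        np.savez(
            path,
            matrix=G.matrix,
            provenance=np.frombuffer(
                json.dumps(G.provenance).encode(), dtype=np.uint8
            ),
        )


def read_leadfield(path: str) -> LeadField:
    if str(path).endswith(".tsv"):
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#"):
                raise ValueError("missing lead-field TSV header line")
            fields = dict(
                kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
            )
            q, p = int(fields["q"]), int(fields["p"])
            rows = []
            for ln, line in enumerate(fh, start=2):
                vals = line.split()
                if len(vals) != p:
                    raise ValueError(
                        f"row {ln}: expected {p} columns, got {len(vals)}"
                    )
                rows.append([float(v) for v in vals])
        if len(rows) != q:
            raise ValueError(f"expected {q} rows, got {len(rows)}")
        return LeadField(
            matrix=np.asarray(rows),
            provenance={"units": fields.get("units", "T_per_Am"), "path": str(path)},
        )
    import json

    if not str(path).endswith(".npz"):
        path = str(path) + ".npz"
    with np.load(path) as data:
        matrix = data["matrix"]
        provenance = json.loads(bytes(data["provenance"]).decode())
    return LeadField(matrix=matrix, provenance=provenance)
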