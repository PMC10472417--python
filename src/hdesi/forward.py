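"""Electrode montage, source grid, three-shell head model and analytic lead fields.

Geometry lives in a RAS head frame (x right, y anterior, z superior) with the
origin at the common center of three concentric spherical shells (brain, skull,
scalp).  All positions are in millimeters; potentials are in microvolt per
nanoampere-meter of dipole moment, in the average-reference space.

The forward solution is the classical series expansion for a current dipole
inside concentric conducting spheres.  Per spherical-harmonic degree ``n`` a
small boundary-value problem couples the shells; the resulting transfer factor
multiplies the free-medium multipole term.  With equal conductivities the
series reduces to the homogeneous conducting sphere, for which a closed form
exists (:func:`potential_homogeneous_sphere`) — that closed form is kept
independent of the series code so either can check the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = [
    "ElectrodeArray",
    "ThreeShellHeadModel",
    "SourceGrid",
    "LeadField",
    "build_electrode_array",
    "align_to_fiducials",
    "build_source_grid",
    "compute_leadfield",
    "potential_homogeneous_sphere",
]

#: minimal clearance between a source and the brain shell (mm); the series
#: diverges as the source approaches the boundary, so this is enforced hard.
SOURCE_MARGIN_MM = 2.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class ThreeShellHeadModel:
    """Concentric brain/skull/scalp spheres with piecewise conductivity."""

    radii_mm: tuple[float, float, float] = (80.0, 85.0, 92.0)
    conductivities_S_per_m: tuple[float, float, float] = (0.33, 0.004, 0.33)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_mm, float)
        if r.shape != (3,) or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ParameterError(
                f"radii must be three positive increasing values, got {self.radii_mm}"
            )
        s = np.asarray(self.conductivities_S_per_m, float)
        if s.shape != (3,) or np.any(s <= 0):
            raise ParameterError(
                f"conductivities must be three positive values, got {self.conductivities_S_per_m}"
            )

    @property
    def brain_radius_mm(self) -> float:
        return float(self.radii_mm[0])

    @property
    def scalp_radius_mm(self) -> float:
        return float(self.radii_mm[2])


@dataclass(frozen=True)
class ElectrodeArray:
    """Scalp electrodes plus the three anatomical fiducials, in mm."""

    channel_ids: tuple[str, ...]
    positions: np.ndarray  # (n, 3)
    fiducials: dict[str, np.ndarray] = field(default_factory=dict)  # nasion/lpa/rpa
    scalp_radius_mm: float = 92.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ParameterError("positions must be an (n, 3) array")
        if len(self.channel_ids) != pos.shape[0]:
            raise ParameterError("channel_ids and positions disagree in length")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ParameterError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)


@dataclass(frozen=True)
class SourceGrid:
    """Regular axis-aligned lattice of candidate source points inside the brain."""

    spacing_mm: float
    positions: np.ndarray  # (n, 3), row-major over (x, y, z)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, float))

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class LeadField:
    """Average-referenced gain matrix, channels x (3 * n_sources), uV per nAm."""

    gain: np.ndarray
    electrodes: ElectrodeArray
    grid: SourceGrid
    head: ThreeShellHeadModel
    n_terms: int

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1] // 3

    def source_gain(self, index: int) -> np.ndarray:
        """The (n_channels, 3) block for one grid point."""
        return self.gain[:, 3 * index : 3 * index + 3]


def build_electrode_array(
    n_channels: int = 256,
    coverage_polar_deg: float = 140.0,
    scalp_radius_mm: float = 92.0,
) -> ElectrodeArray:
    """Quasi-uniform (spherical Fibonacci) cap of electrodes on the scalp sphere.

    The cap covers polar angles ``[0, coverage_polar_deg]`` measured from +z.
    Deterministic: the same arguments always give the same coordinates.
    """
    if n_channels < 8:
        raise ParameterError(f"need at least 8 channels, got {n_channels}")
    if not 0 < coverage_polar_deg <= 160:
        raise ParameterError(
            f"coverage_polar_deg must be in (0, 160], got {coverage_polar_deg}"
        )
    z_lo = np.cos(np.deg2rad(coverage_polar_deg))
    i = np.arange(n_channels)
    z = 1.0 - (1.0 - z_lo) * (i + 0.5) / n_channels
    phi = i * _GOLDEN_ANGLE
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pos = scalp_radius_mm * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    width = len(str(n_channels))
    ids = tuple(f"E{k + 1:0{width}d}" for k in range(n_channels))
    fiducials = {
        "nasion": np.array([0.0, scalp_radius_mm, 0.0]),
        "lpa": np.array([-scalp_radius_mm, 0.0, 0.0]),
        "rpa": np.array([scalp_radius_mm, 0.0, 0.0]),
    }
    return ElectrodeArray(ids, pos, fiducials, scalp_radius_mm)


def _rigid_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with dst ~= src @ R.T + t (Kabsch)."""
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    h = src_c.T @ dst_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = dst.mean(axis=0) - rot @ src.mean(axis=0)
    return rot, t


def align_to_fiducials(
    array: ElectrodeArray,
    nasion: np.ndarray,
    lpa: np.ndarray,
    rpa: np.ndarray,
) -> ElectrodeArray:
    """Rigidly move the array so its stored fiducials land on the targets.

    Rotation + translation only (no scaling), least squares over the three
    fiducial pairs.  Raises :class:`GeometryError` for collinear fiducials.
    """
    targets = np.asarray([nasion, lpa, rpa], float)
    if targets.shape != (3, 3):
        raise ParameterError("fiducial targets must be three 3-vectors")
    v1, v2 = targets[1] - targets[0], targets[2] - targets[0]
    if np.linalg.norm(np.cross(v1, v2)) < 1e-9 * max(
        np.linalg.norm(v1), np.linalg.norm(v2), 1.0
    ):
        raise GeometryError("fiducial targets are collinear")
    stored = np.asarray(
        [array.fiducials["nasion"], array.fiducials["lpa"], array.fiducials["rpa"]],
        float,
    )
    rot, t = _rigid_fit(stored, targets)
    new_pos = array.positions @ rot.T + t
    new_fid = {k: rot @ np.asarray(v, float) + t for k, v in array.fiducials.items()}
    return replace(array, positions=new_pos, fiducials=new_fid)


def build_source_grid(head: ThreeShellHeadModel, spacing_mm: float = 5.0) -> SourceGrid:
    """All lattice points with |r| <= brain_radius - 2 mm, lattice centered on origin.

    Indexing is 0-based, row-major over (x, y, z).
    """
    if spacing_mm <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing_mm}")
    r_max = head.brain_radius_mm - SOURCE_MARGIN_MM
    k = int(np.floor(r_max / spacing_mm))
    axis = np.arange(-k, k + 1) * spacing_mm
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(pts, axis=1) <= r_max
    return SourceGrid(spacing_mm=spacing_mm, positions=pts[inside])


# --------------------------------------------------------------------------
# analytic forward solutions
# --------------------------------------------------------------------------


def _shell_transfer_factors(head: ThreeShellHeadModel, n_terms: int) -> np.ndarray:
    """Per-degree transfer factor T_n for the three-shell sphere.

    T_n multiplies the free-medium multipole coefficient of degree ``n`` (in
    radii scaled by the scalp radius) to give the scalp-surface coefficient.
    For equal conductivities T_n = (2n+1)/n, the homogeneous-sphere value.
    """
    s1, s2, s3 = head.conductivities_S_per_m
    rho1, rho2 = (
        head.radii_mm[0] / head.radii_mm[2],
        head.radii_mm[1] / head.radii_mm[2],
    )
    out = np.empty(n_terms)
    for i, n in enumerate(range(1, n_terms + 1)):
        f = lambda r: r**n
        g = lambda r: r ** -(n + 1)
        fp = lambda r: n * r ** (n - 1)
        gp = lambda r: -(n + 1) * r ** -(n + 2)
        # unknowns [A1, A2, B2, A3, B3]; source coefficient B1 = 1 in shell 1
        a = np.array(
            [
                [f(rho1), -f(rho1), -g(rho1), 0.0, 0.0],
                [s1 * fp(rho1), -s2 * fp(rho1), -s2 * gp(rho1), 0.0, 0.0],
                [0.0, f(rho2), g(rho2), -f(rho2), -g(rho2)],
                [0.0, s2 * fp(rho2), s2 * gp(rho2), -s3 * fp(rho2), -s3 * gp(rho2)],
                [0.0, 0.0, 0.0, fp(1.0), gp(1.0)],
            ]
        )
        b = np.array([-g(rho1), -s1 * gp(rho1), 0.0, 0.0, 0.0])
        x = np.linalg.solve(a, b)
        # surface value A3 + B3 (the primary term lives only in shell 1)
        out[i] = x[3] + x[4]
    return out


def potential_homogeneous_sphere(
    elec_pos_mm: np.ndarray,
    dipole_pos_mm: np.ndarray,
    moment_nAm: np.ndarray,
    sigma_S_per_m: float,
    radius_mm: float,
) -> np.ndarray:
    """Closed-form scalp potential (uV) of a dipole in a homogeneous sphere.

    Electrodes must lie on the sphere surface.  This is the textbook closed
    form (image-series summed analytically); it shares no code with the shell
    series and serves as its oracle.
    """
    r = np.atleast_2d(np.asarray(elec_pos_mm, float)) / 1000.0
    r0 = np.asarray(dipole_pos_mm, float) / 1000.0
    q = np.asarray(moment_nAm, float) * 1e-9  # A m
    big_r = radius_mm / 1000.0
    d_vec = r - r0
    d = np.linalg.norm(d_vec, axis=1)
    denom = big_r**2 - r @ r0 + big_r * d
    v = (1.0 / (4.0 * np.pi * sigma_S_per_m)) * (
        2.0 * (d_vec @ q) / d**3
        + (r @ q + big_r * (d_vec @ q) / d) / (big_r * denom)
    )
    return v * 1e6  # volts -> uV


def _legendre_terms(x: np.ndarray, n_terms: int):
    """Yield (n, P_n(x), P_n^1(x)) for n = 1..n_terms.

    P_n^1 here is the associated Legendre function *without* the
    Condon-Shortley phase (P_1^1 = sqrt(1 - x^2)).
    """
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    p_prev, p_cur = np.ones_like(x), x.copy()  # P_0, P_1
    q_prev, q_cur = np.zeros_like(x), s.copy()  # P_0^1, P_1^1
    for n in range(1, n_terms + 1):
        yield n, p_cur, q_cur
        p_nxt = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        q_nxt = ((2 * n + 1) * x * q_cur - (n + 1) * q_prev) / n
        p_prev, p_cur = p_cur, p_nxt
        q_prev, q_cur = q_cur, q_nxt


def compute_leadfield(
    head: ThreeShellHeadModel,
    electrodes: ElectrodeArray,
    grid: SourceGrid,
    n_terms: int = 60,
) -> LeadField:
    """Average-referenced gain matrix for unit x/y/z dipoles at every grid point.

    Series truncation at ``n_terms``: each term decays like (b/R)^(n-1) with b
    the source eccentricity, so for sources kept 2 mm inside the brain shell
    the tail beyond the default 60 terms is negligible (checked by the n_terms
    doubling property test).
    """
    if n_terms < 20:
        raise ParameterError(f"n_terms must be >= 20, got {n_terms}")
    scalp_r = head.scalp_radius_mm
    if np.any(np.abs(np.linalg.norm(electrodes.positions, axis=1) - scalp_r) > 0.1):
        raise GeometryError("electrodes must lie on the scalp sphere (0.1 mm tol)")
    src = grid.positions
    b = np.linalg.norm(src, axis=1)
    if np.any(b > head.brain_radius_mm - SOURCE_MARGIN_MM + 1e-9):
        raise GeometryError(
            f"sources must stay {SOURCE_MARGIN_MM} mm inside the brain shell"
        )

    n_el, n_src = electrodes.n_channels, src.shape[0]
    t_n = _shell_transfer_factors(head, n_terms)

    r_hat_e = electrodes.positions / scalp_r  # (E, 3) unit
    r_hat0 = np.zeros_like(src)
    nz = b > 1e-9
    r_hat0[nz] = src[nz] / b[nz, None]
    r_hat0[~nz] = [0.0, 0.0, 1.0]  # direction irrelevant at the exact center

    cosg = np.clip(r_hat_e @ r_hat0.T, -1.0, 1.0)  # (E, S)
    beta = b / scalp_r  # (S,)

    s1 = np.zeros((n_el, n_src))  # sum of T_n beta^(n-1) n P_n
    s2 = np.zeros((n_el, n_src))  # sum of T_n beta^(n-1) P_n^1
    beta_pow = np.ones(n_src)  # beta^(n-1)
    for n, p_n, p_n1 in _legendre_terms(cosg, n_terms):
        w = t_n[n - 1] * beta_pow
        s1 += (n * w) * p_n
        s2 += w * p_n1
        beta_pow = beta_pow * beta

    # tangential unit vector in the (source, electrode) plane
    sing = np.sqrt(np.clip(1.0 - cosg * cosg, 0.0, None))
    inv_sing = np.where(sing > 1e-12, 1.0 / np.maximum(sing, 1e-300), 0.0)
    s2 = s2 * inv_sing  # fold 1/sin(gamma) of t_hat into the tangential sum

    sigma1 = head.conductivities_S_per_m[0]
    scale = 1e-9 / (4.0 * np.pi * sigma1 * (scalp_r / 1000.0) ** 2) * 1e6  # uV per nAm

    gain = np.empty((n_el, 3 * n_src))
    for j in range(3):
        t_comp = r_hat_e[:, j][:, None] - cosg * r_hat0[:, j][None, :]
        gain[:, j::3] = scale * (s1 * r_hat0[:, j][None, :] + s2 * t_comp)
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return LeadField(gain=gain, electrodes=electrodes, grid=grid, head=head, n_terms=n_terms)
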