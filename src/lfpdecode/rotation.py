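"""Rotational structure and areal velocity of multichannel low-frequency LFP.

Because the spike-related slow potentials mix a few sources with different
spatio-temporal profiles, movement-locked low-frequency oscillations appear
with different phases on different channels; the LFP trajectory therefore
rotates in channel space. Two complementary extractors are provided:

* jPCA: fit skew-symmetric linear dynamics dx/dt ~ M x to the PCA-reduced
  LFP (closed-form least squares over the skew basis) and take the planes of
  its conjugate eigenvector pairs as the planes of maximal rotation.
* areal velocity (AV): the area swept per unit time by the LFP projected
  into a plane spanned by orthonormal u, v:

      AV_{u,v} = 1/2 [(u.l)(v.l_dot) - (v.l)(u.l_dot)]
               = sum_{i<j} (u_i v_j - u_j v_i) AV_{i,j},
      AV_{i,j} = 1/2 (l_i l_dot_j - l_j l_dot_i).

AV rejects all in-phase components shared across channels (regardless of
per-channel gain), has zero time-mean for phase-unstructured noise, scales
as amplitude squared, and is antisymmetric under index swap and time
reversal. In a 3-component space the cross product 1/2 x x x_dot is a vector
whose magnitude is the planar AV in the instantaneous rotation plane and
whose direction is the rotation axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import LfpRecording, ValidationError
from .preprocess import PcaBasis, bandpass, fit_pca, time_derivative

__all__ = [
    "ProjectionPlane",
    "ArealVelocitySignal",
    "ArealVelocityVector",
    "fit_jpca",
    "areal_velocity_plane",
    "areal_velocity_pairs",
    "plane_trajectory",
    "plane_decomposition_check",
    "areal_velocity_vector3",
    "banded_areal_velocity",
]


@dataclass
class ProjectionPlane:
    """A plane in channel space spanned by orthonormal vectors ``u``, ``v``.

    ``offset`` (optional) is subtracted from the LFP before projection (the
    PCA mean for jPCA-derived planes). ``freq_hz`` is the rotation frequency
    estimate from the jPCA eigenvalue, when available.
    """

    u: np.ndarray
    v: np.ndarray
    kind: str = "custom"
    freq_hz: float | None = None
    offset: np.ndarray | None = None

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for name, w in (("u", self.u), ("v", self.v)):
            if abs(np.linalg.norm(w) - 1) > 1e-10:
                raise ValidationError(f"plane vector {name} is not unit length")
        if abs(self.u @ self.v) > 1e-10:
            raise ValidationError("plane vectors are not orthogonal")


@dataclass
class ArealVelocitySignal:
    """Area swept per unit time, (LFP units)^2 / s."""

    values: np.ndarray
    fs: float
    t_start: float = 0.0
    label: str = ""
    pair: tuple | None = None


@dataclass
class ArealVelocityVector:
    """Time x 3 series (AV_23, AV_31, AV_12) of 1/2 x cross x_dot."""

    values: np.ndarray
    fs: float
    t_start: float = 0.0

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=1)


# ---------------------------------------------------------------------------
# jPCA
# ---------------------------------------------------------------------------


def _skew_basis(n: int):
    return list(combinations(range(n), 2))


def fit_jpca(
    lfp: LfpRecording, n_pcs: int = 6, n_planes: int = 2
) -> tuple[list[ProjectionPlane], PcaBasis]:
    """Find the planes best capturing rotational structure.

    The LFP (already LMP-filtered by the caller) is reduced to ``n_pcs``
    principal components; skew-symmetric dynamics dx/dt ~ M x are fitted in
    closed form over the skew basis, and each conjugate-imaginary eigenvalue
    pair of M yields one plane (orthonormalized real/imaginary eigenvector
    parts, mapped back to channel space), ordered by |eigenvalue|. Plane
    orientation is fixed so the mean AV over the fitting span is
    non-negative. Returns the planes and the PCA basis used.
    """
    if n_pcs > lfp.n_channels:
        raise ValidationError("n_pcs exceeds channel count")
    basis = fit_pca(lfp, n_pcs)
    x = (lfp.samples - basis.mean) @ basis.components.T
    xdot = np.gradient(x, 1.0 / lfp.fs, axis=0)

    S = x.T @ x
    C = xdot.T @ x
    pairs = _skew_basis(n_pcs)
    K = len(pairs)
    if n_planes > n_pcs // 2:
        raise ValidationError(
            f"n_planes={n_planes} exceeds the {n_pcs // 2} planes available from {n_pcs} PCs"
        )
    B = np.zeros((K, n_pcs, n_pcs))
    for a, (i, j) in enumerate(pairs):
        B[a, i, j] = 1.0
        B[a, j, i] = -1.0
    H = np.einsum("aij,jk,bik->ab", B, S, B, optimize=True)
    rhs = np.array([C[i, j] - C[j, i] for (i, j) in pairs])
    m = np.linalg.solve(H, rhs)
    M = np.einsum("a,aij->ij", m, B)  # exactly skew-symmetric by construction

    w, V = np.linalg.eig(M)
    order = np.argsort(-np.abs(w.imag))
    planes: list[ProjectionPlane] = []
    used = set()
    for idx in order:
        if len(planes) == n_planes:
            break
        om = w[idx].imag
        if abs(om) < 1e-12 * max(1.0, np.abs(w.imag).max()):
            warnings.warn("ignoring near-zero jPCA eigenvalue (odd effective dimension)")
            continue
        key = round(abs(om), 12)
        if key in used:  # conjugate partner of an already-used pair
            continue
        used.add(key)
        q = V[:, idx]
        a, b = np.real(q), np.imag(q)
        # orthonormalize the pair (Gram-Schmidt)
        a = a / np.linalg.norm(a)
        b = b - (b @ a) * a
        b = b / np.linalg.norm(b)
        u_ch = basis.components.T @ a
        v_ch = basis.components.T @ b
        plane = ProjectionPlane(
            u=u_ch, v=v_ch, kind="jpca", freq_hz=abs(om) / (2 * np.pi), offset=basis.mean
        )
        if np.mean(areal_velocity_plane(lfp, plane).values) < 0:
            plane = ProjectionPlane(
                u=u_ch, v=-v_ch, kind="jpca", freq_hz=plane.freq_hz, offset=basis.mean
            )
        planes.append(plane)
    if len(planes) < n_planes:
        raise ValidationError(f"only {len(planes)} rotational planes available")
    return planes, basis


# ---------------------------------------------------------------------------
# areal velocity
# ---------------------------------------------------------------------------


def areal_velocity_plane(lfp: LfpRecording, plane: ProjectionPlane) -> ArealVelocitySignal:
    """AV_{u,v}(t) = 1/2 [(u.l)(v.l_dot) - (v.l)(u.l_dot)].

    Counter-clockwise rotation in (u, v) coordinates is positive. The plane's
    stored offset (PCA mean), if any, is subtracted before projection.
    """
    if plane.u.size != lfp.n_channels:
        raise ValidationError("plane dimension does not match channel count")
    x = lfp.samples if plane.offset is None else lfp.samples - plane.offset
    a = x @ plane.u
    b = x @ plane.v
    dt = 1.0 / lfp.fs
    adot = np.gradient(a, dt)
    bdot = np.gradient(b, dt)
    av = 0.5 * (a * bdot - b * adot)
    return ArealVelocitySignal(
        values=av, fs=lfp.fs, t_start=lfp.t_start, label=f"plane:{plane.kind}"
    )


def plane_trajectory(lfp: LfpRecording, plane: ProjectionPlane) -> LfpRecording:
    """The 2-D projected trajectory (u.l, v.l) as a two-channel recording."""
    if plane.u.size != lfp.n_channels:
        raise ValidationError("plane dimension does not match channel count")
    x = lfp.samples if plane.offset is None else lfp.samples - plane.offset
    return lfp.copy_with(np.column_stack([x @ plane.u, x @ plane.v]), channel_ids=["u", "v"])


def areal_velocity_pairs(lfp: LfpRecording, pairs="all") -> list[ArealVelocitySignal]:
    """Pairwise AV_{i,j} = 1/2 (l_i l_dot_j - l_j l_dot_i) for channel pairs.

    ``pairs="all"`` yields all N(N-1)/2 pairs in lexicographic order (i < j),
    indices referring to the recording's channel order. AV_{j,i} = -AV_{i,j};
    only i < j is computed (i = j is identically zero and disallowed).
    """
    if pairs == "all":
        pair_list = list(combinations(range(lfp.n_channels), 2))
    else:
        pair_list = [tuple(p) for p in pairs]
    ldot = time_derivative(lfp).samples
    l = lfp.samples
    out = []
    for i, j in pair_list:
        if i == j:
            raise ValidationError(f"pair ({i},{j}): identical indices are disallowed")
        if not (0 <= i < lfp.n_channels and 0 <= j < lfp.n_channels):
            raise ValidationError(f"pair ({i},{j}) out of range for {lfp.n_channels} channels")
        av = 0.5 * (l[:, i] * ldot[:, j] - l[:, j] * ldot[:, i])
        out.append(
            ArealVelocitySignal(
                values=av, fs=lfp.fs, t_start=lfp.t_start, label=f"pair:{i},{j}", pair=(i, j)
            )
        )
    return out


def plane_decomposition_check(lfp: LfpRecording, plane: ProjectionPlane) -> float:
    """Max |AV_plane - sum_{i<j} (u_i v_j - u_j v_i) AV_{i,j}| over time.

    The identity is algebraic and should hold to ~1e-9 of the signal scale;
    both sides are evaluated on the offset-centered LFP.
    """
    x = lfp.samples if plane.offset is None else lfp.samples - plane.offset
    centered = lfp.copy_with(x)
    target = areal_velocity_plane(
        centered, ProjectionPlane(u=plane.u, v=plane.v, kind=plane.kind)
    ).values
    total = np.zeros_like(target)
    for sig_av in areal_velocity_pairs(centered, "all"):
        i, j = sig_av.pair
        w = plane.u[i] * plane.v[j] - plane.u[j] * plane.v[i]
        total += w * sig_av.values
    return float(np.max(np.abs(target - total)))


def areal_velocity_vector3(lfp: LfpRecording, basis: PcaBasis) -> ArealVelocityVector:
    """3-D areal-velocity vector v(t) = 1/2 x(t) x x_dot(t) of the projection.

    Requires a 3-component basis. Component k equals the pairwise AV of the
    projected coordinates in the plane normal to axis k, so the magnitude is
    the planar AV in the instantaneous rotation plane and the direction is
    the rotation axis.
    """
    if basis.n_components != 3:
        raise ValidationError("areal_velocity_vector3 requires exactly 3 components")
    x = (lfp.samples - basis.mean) @ basis.components.T
    xdot = np.gradient(x, 1.0 / lfp.fs, axis=0)
    v = 0.5 * np.cross(x, xdot)
    return ArealVelocityVector(values=v, fs=lfp.fs, t_start=lfp.t_start)


def banded_areal_velocity(
    lfp: LfpRecording, plane: ProjectionPlane, band: tuple
) -> ArealVelocitySignal:
    """Band-limited AV: zero-phase band-pass per channel, then planar AV.

    The band-pass removes DC, so the plane's offset is not re-subtracted.
    """
    f_lo, f_hi = band
    filtered = bandpass(lfp, f_lo, f_hi)
    flat_plane = ProjectionPlane(u=plane.u, v=plane.v, kind=plane.kind, freq_hz=plane.freq_hz)
    out = areal_velocity_plane(filtered, flat_plane)
    out.label = f"{out.label}:band{f_lo}-{f_hi}"
    return out
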