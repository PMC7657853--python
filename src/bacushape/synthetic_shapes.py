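"""Synthetic solids with known reference volumes.

Analytic primitives (sphere, cuboid, torus, cylinder) and a parametric
bone-like solid built by constructive solid geometry on inclusion tests:
a curved cylindrical shaft, minus a ventral groove channel running to the
distal tip, plus an optional toroidal distal hook, an optional two-prong
distal bifurcation, and optional sinusoidal basal rugosity.  The feature
ladder deliberately mimics the morphology that makes real bacula complex —
deep urethral grooves, apical hooks, rugose attachment sites — while keeping
the true solid volume controllable: primitives have closed-form volumes and
the composite solid is measured by fine voxelization of the same inclusion
test that the point sampler uses, so reference volumes are independent of
any meshing step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shape_io import PointCloud

__all__ = ["ShapeSpec", "make_primitive", "make_baculum", "BaculumSolid"]


@dataclass
class ShapeSpec:
    """Parameters of a synthetic solid.

    For ``kind='baculum'`` all feature parameters default to zero, which
    recovers a plain straight cylinder of length ``shaft_length`` and radius
    ``shaft_radius``.  ``groove_depth`` is the bite depth as a fraction of the
    shaft radius (∈ [0, 1)); ``hook_angle`` is the arc swept by the distal
    hook in degrees with bend radius ``hook_radius``; ``bifurcation_frac`` is
    the distal fraction of the shaft split into two prongs; ``rugosity_amp``
    is the relative radius modulation over the basal quarter.
    """

    kind: str = "baculum"
    size: tuple[float, ...] = (1.0,)            # primitive size parameters
    shaft_length: float = 1.0
    shaft_radius: float = 0.08
    curvature_angle: float = 0.0                # radians of total centerline turn
    groove_depth: float = 0.0
    hook_angle: float = 0.0                     # degrees
    hook_radius: float = 0.08                   # tight curl: slot, not open void
    bifurcation_frac: float = 0.0
    rugosity_amp: float = 0.0
    n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("size parameters must be positive")
        if self.shaft_length <= 0 or self.shaft_radius <= 0:
            raise ValueError("shaft dimensions must be positive")
        if not 0 <= self.groove_depth < 1:
            raise ValueError("groove depth fraction must be in [0, 1)")
        if not 0 <= self.bifurcation_frac < 1:
            raise ValueError("bifurcation fraction must be in [0, 1)")
        if self.hook_angle < 0 or self.hook_radius <= 0:
            raise ValueError("invalid hook parameters")
        if self.hook_angle > 0 and self.hook_radius > self.shaft_length:
            raise ValueError("hook radius exceeds shaft length: "
                             "features geometrically inconsistent")
        if self.rugosity_amp < 0 or self.rugosity_amp >= 1:
            raise ValueError("rugosity amplitude must be in [0, 1)")


# ---------------------------------------------------------------------------
# primitives

def _primitive_inclusion(spec: ShapeSpec):
    kind, size = spec.kind, spec.size
    if kind == "sphere":
        (r,) = size
        return (lambda p: (p ** 2).sum(1) < r * r,
                4.0 / 3.0 * np.pi * r ** 3,
                np.array([[-r, -r, -r], [r, r, r]]))
    if kind == "cuboid":
        a, b, c = size
        half = np.array([a, b, c]) / 2
        return (lambda p: np.all(np.abs(p) < half, axis=1),
                a * b * c, np.array([-half, half]))
    if kind == "torus":
        R, r = size
        def inc(p):
            rho = np.hypot(p[:, 0], p[:, 1])
            return (rho - R) ** 2 + p[:, 2] ** 2 < r * r
        return (inc, 2 * np.pi ** 2 * R * r * r,
                np.array([[-(R + r)] * 2 + [-r], [R + r, R + r, r]]))
    if kind == "cylinder":
        r, L = size
        def inc(p):
            return (p[:, 0] ** 2 + p[:, 1] ** 2 < r * r) & \
                   (p[:, 2] > 0) & (p[:, 2] < L)
        return (inc, np.pi * r * r * L,
                np.array([[-r, -r, 0.0], [r, r, L]]))
    raise ValueError(f"unknown primitive kind {kind!r}")


def _rejection_sample(inclusion, bbox: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    lo, hi = bbox
    out: list[np.ndarray] = []
    got = 0
    rate = 0.3
    while got < n:
        batch = int(min(4_000_000, max(8192, (n - got) / max(rate, 1e-3) * 1.3)))
        cand = rng.uniform(lo, hi, size=(batch, 3))
        keep = cand[inclusion(cand)]
        rate = max(keep.shape[0] / batch, 1e-4)
        out.append(keep)
        got += keep.shape[0]
    return np.vstack(out)[:n]


def make_primitive(spec: ShapeSpec) -> PointCloud:
    """Uniform interior points of an analytic primitive; V_ref closed-form."""
    if spec.kind not in ("sphere", "cuboid", "torus", "cylinder"):
        raise ValueError(f"kind {spec.kind!r} is not a primitive")
    inclusion, v_ref, bbox = _primitive_inclusion(spec)
    rng = np.random.default_rng(spec.seed)
    pts = _rejection_sample(inclusion, bbox, spec.n, rng)
    return PointCloud(pts, v_ref, provenance="synthetic", seed=spec.seed)


# ---------------------------------------------------------------------------
# parametric baculum

def _arc_frame(p: np.ndarray, center: np.ndarray, e1: np.ndarray,
               e2: np.ndarray, radius: float, t_max: float):
    """Local coordinates of points relative to a circular arc.

    The arc is ``q(t) = center + radius (e1 cos t + e2 sin t)``, t ∈ [0, t_max],
    in the plane spanned by e1, e2 (their common normal carries ``v``).
    Returns (t_clamped, inside_span, u, v) where ``u`` is the signed radial
    excess in the bend plane and ``v`` the out-of-plane offset.
    """
    normal = np.cross(e1, e2)
    w = p - center
    a1, a2 = w @ e1, w @ e2
    v = w @ normal
    t = np.arctan2(a2, a1)
    t = np.where(t < 0, t + 2 * np.pi, t)
    inside = t <= t_max
    tc = np.clip(t, 0.0, t_max)
    rho = np.hypot(a1, a2)
    u = rho - radius
    return tc, inside, u, v


class BaculumSolid:
    """Inclusion-test CSG solid for a parametric bone-like shape."""

    def __init__(self, spec: ShapeSpec):
        if spec.kind != "baculum":
            raise ValueError("spec.kind must be 'baculum'")
        self.spec = spec
        L, r = spec.shaft_length, spec.shaft_radius
        phi = spec.curvature_angle
        self._straight = phi < 1e-9
        if not self._straight:
            self.Rc = L / phi
            self.phi = phi
            self.center = np.array([self.Rc, 0.0, 0.0])
            self.e1 = np.array([-1.0, 0.0, 0.0])
            self.e2 = np.array([0.0, 0.0, 1.0])
            # distal endpoint and tangent
            self.tip = self.center + self.Rc * (
                self.e1 * np.cos(phi) + self.e2 * np.sin(phi))
            self.tip_tangent = -self.e1 * np.sin(phi) + self.e2 * np.cos(phi)
            self.tip_outward = (self.tip - self.center) / self.Rc
        else:
            self.tip = np.array([0.0, 0.0, L])
            self.tip_tangent = np.array([0.0, 0.0, 1.0])
            self.tip_outward = np.array([-1.0, 0.0, 0.0])
        if spec.hook_angle > 0:
            Rh = spec.hook_radius
            self.hook_center = self.tip + Rh * self.tip_outward
            self.hook_e1 = -self.tip_outward
            self.hook_e2 = self.tip_tangent
            self.hook_tmax = np.deg2rad(spec.hook_angle)

    # -- local shaft coordinates -------------------------------------------
    def _shaft_coords(self, p: np.ndarray):
        """Arc-length fraction s ∈ [0,1], radial u (ventral +), lateral v."""
        L = self.spec.shaft_length
        if self._straight:
            s = p[:, 2] / L
            inside = (p[:, 2] >= 0) & (p[:, 2] <= L)
            u, v = -p[:, 0], p[:, 1]
            return np.clip(s, 0, 1), inside, u, v
        t, inside, u, v = _arc_frame(p, self.center, self.e1, self.e2,
                                     self.Rc, self.phi)
        return t / self.phi, inside, u, v

    def inclusion(self, p: np.ndarray) -> np.ndarray:
        sp = self.spec
        L, r = sp.shaft_length, sp.shaft_radius
        s, span, u, v = self._shaft_coords(p)
        r_eff = np.full(p.shape[0], r)
        if sp.rugosity_amp > 0:
            psi = np.arctan2(v, u)
            basal = s < 0.25
            bump = sp.rugosity_amp * np.sin(6 * psi) * \
                np.sin(np.pi * np.clip(s / 0.25, 0, 1))
            r_eff = np.where(basal, r * (1 + bump), r_eff)
        in_tube = span & (u * u + v * v < r_eff * r_eff)
        if sp.bifurcation_frac > 0:
            z = (s - (1 - sp.bifurcation_frac)) / sp.bifurcation_frac
            bif = span & (z > 0)
            off = 1.4 * r * np.clip(z, 0, 1)
            prong = (u * u + (np.abs(v) - off) ** 2) < (0.7 * r) ** 2
            in_tube = np.where(bif, span & prong, in_tube)
        body = in_tube
        if sp.groove_depth > 0:
            # ventral channel: circle of radius d·r centered on the surface
            d = sp.groove_depth
            groove = span & ((u - r) ** 2 + v * v < (d * r) ** 2)
            body = body & ~groove
        if sp.hook_angle > 0:
            _, hin, hu, hv = _arc_frame(p, self.hook_center, self.hook_e1,
                                        self.hook_e2, sp.hook_radius,
                                        self.hook_tmax)
            body = body | (hin & (hu * hu + hv * hv < r * r))
        return body

    def bbox(self) -> np.ndarray:
        sp = self.spec
        L, r = sp.shaft_length, sp.shaft_radius
        # hook lives in the x–z bend plane; lateral (y) extent is tube-only
        pad = 2.5 * r + (sp.hook_radius * 2 if sp.hook_angle > 0 else 0)
        pad_y = 2.5 * r
        if self._straight:
            lo = np.array([-pad, -pad_y, -pad])
            hi = np.array([pad, pad_y, L + pad])
        else:
            xs = self.Rc * (1 - np.cos(np.linspace(0, self.phi, 64)))
            zs = self.Rc * np.sin(np.linspace(0, self.phi, 64))
            lo = np.array([xs.min() - pad, -pad_y, min(zs.min(), 0) - pad])
            hi = np.array([xs.max() + pad, pad_y, zs.max() + pad])
        return np.array([lo, hi])

    def volume(self, pitch: float | None = None) -> float:
        """Reference volume by voxelizing the inclusion test (z-slab chunks)."""
        sp = self.spec
        if pitch is None:
            pitch = sp.shaft_radius / 50.0
        lo, hi = self.bbox()
        nx, ny, nz = (np.ceil((hi - lo) / pitch)).astype(int)
        xs = lo[0] + (np.arange(nx) + 0.5) * pitch
        ys = lo[1] + (np.arange(ny) + 0.5) * pitch
        zs = lo[2] + (np.arange(nz) + 0.5) * pitch
        count = 0
        chunk = max(1, int(4_000_000 // (nx * ny)))
        for k0 in range(0, nz, chunk):
            zc = zs[k0:k0 + chunk]
            X, Y, Z = np.meshgrid(xs, ys, zc, indexing="ij")
            pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
            count += int(self.inclusion(pts).sum())
        return count * pitch ** 3


def make_baculum(spec: ShapeSpec, pitch: float | None = None) -> PointCloud:
    """Uniform interior points of the parametric solid; V_ref by voxelization."""
    solid = BaculumSolid(spec)
    v_ref = solid.volume(pitch=pitch)
    if v_ref <= 0:
        raise ValueError("solid has zero volume")
    rng = np.random.default_rng(spec.seed)
    pts = _rejection_sample(solid.inclusion, solid.bbox(), spec.n, rng)
    return PointCloud(pts, v_ref, provenance="synthetic", seed=spec.seed)
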