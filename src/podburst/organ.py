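"""Organ-scale model: the excised valve as an elastica with intrinsic
curvature, extensometer-curve processing and bending-stiffness fitting.

A freshly excised valve is curled (intrinsic curvature ``kappa_hat``,
set by the layer-strain mismatch).  Clamped in an extensometer and
pulled flat, the axial force it exerts is the derivative of its bending
energy with respect to the end-to-end distance.  The clamped-clamped
boundary-value problem is solved here by energy minimisation over a
discretized inextensible rod; because the equilibrium *shape* at a given
end-to-end distance does not depend on the bending stiffness ``B`` (B
multiplies the whole energy), the force curve is exactly linear in B,
which makes the stiffness fit a linear regression on a precomputed
shape-function ``f(d)`` with ``F = B f(d)``.

Raw extensometer curves include the compliance of the setup (sensor,
clamps, actuator): after the valve is straight, further machine
displacement loads the series spring, producing a linear ramp up to
valve rupture.  ``correct_setup_compliance`` recovers that slope and
removes the setup travel ``F / k_setup`` from the displacement axis.

The fitted whole-valve ``B`` is converted to an exocarp Young's modulus
by inverting the trilayer effective bending stiffness, and to the
exocarp pulling force ``F = E_exo A_exo gamma``, the cross-scale
quantity compared with the pressurized cell-file model.

Curves live in natural units (displacement μm, force mN); the elastica
solver is SI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, minimize

from .energetics import ValveModel, effective_bending_stiffness

__all__ = [
    "ExtensometerCurve", "ElasticaFit", "elastica_force_displacement",
    "elastica_shape_factor", "correct_setup_compliance",
    "fit_bending_stiffness", "exocarp_from_valve",
]


@dataclass
class ExtensometerCurve:
    """Force–displacement record (displacement μm, force mN).

    ``d0`` is the clamp separation at zero displacement (mm) and ``L``
    the valve contour length (mm); ``k_setup`` (mN/μm) is the setup
    stiffness if known, ``rupture_index`` the sample at which the valve
    ruptured (None if not detected/applicable).
    """

    displacement_um: np.ndarray
    force_mN: np.ndarray
    d0_mm: float | None = None
    L_mm: float | None = None
    k_setup: float | None = None
    rupture_index: int | None = None

    def __post_init__(self):
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        self.force_mN = np.asarray(self.force_mN, dtype=float)
        if self.displacement_um.shape != self.force_mN.shape:
            raise ValueError("displacement and force lengths differ")
        # raw (machine) displacement is strictly increasing; corrected
        # curves (k_setup set) may stall or retreat where the setup unloads
        if self.k_setup is None and np.any(np.diff(self.displacement_um) <= 0):
            raise ValueError("displacement must be strictly increasing")


@dataclass(frozen=True)
class ElasticaFit:
    B: float                      # N·m²
    kappa_hat: float              # 1/m
    L: float                      # m
    residual_norm: float          # mN
    B_ci: tuple = (np.nan, np.nan)   # bootstrap 95% CI on B
    E_exocarp: float | None = None   # Pa
    exocarp_force: float | None = None  # N

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("bending stiffness must be positive")


# ---------------------------------------------------------------------------
# elastica boundary-value problem


class _ElasticaSolver:
    """Clamped-clamped inextensible elastica in angle representation.

    Lengths are scaled by the contour length L and the bending modulus
    set to one.  The configuration is the tangent angle per edge; the
    first and last edges are clamped horizontal (the last at ``2 pi k``
    for a branch with ``k`` internal loops — a coiled valve held between
    extensometer clamps keeps its loops until pulled out).  Bending
    energy is quadratic in the angles; the end-to-end closure is imposed
    as two equality constraints and the axial reaction is the closure
    multiplier, i.e. exactly dE*/dd.

    The physical force at end-to-end distance ``d`` is
    ``B / L**2 * solve(d / L)[1]``.
    """

    def __init__(self, kappa_hat: float, L: float, n: int = 80):
        self.kappa_hat = kappa_hat
        self.L = L
        self.n_e = n
        self.h = 1.0 / n
        self.kp = kappa_hat * L               # total intrinsic turn, rad
        self._warm: dict[int, np.ndarray] = {}

    # -- single-branch solve ------------------------------------------
    def _branch_system(self, k: int):
        """Quadratic-energy pieces for branch k: E = 1/2 y'Hy + b'y + c0."""
        n_e, h = self.n_e, self.h
        theta0 = self.kp * h
        m = n_e - 2
        H = (np.diag(np.full(m, 2.0)) + np.diag(np.full(m - 1, -1.0), 1)
             + np.diag(np.full(m - 1, -1.0), -1)) / h
        end = 2.0 * np.pi * k
        # dE/dy_i = (2 phi_i - phi_{i-1} - phi_{i+1}) / h: the theta0 terms
        # cancel at interior junctions; the fixed boundary angles
        # (phi_0 = 0, phi_{n-1} = 2 pi k) move into the linear term
        b = np.zeros(m)
        b[-1] = -end / h
        return H, b, end

    def _solve_branch(self, d: float, k: int):
        """Newton on the KKT system of the quadratic-energy branch."""
        n_e, h = self.n_e, self.h
        m = n_e - 2
        end = 2.0 * np.pi * k
        H, b, _ = self._branch_system(k)

        def phi_of(y):
            return np.concatenate([[0.0], y, [end]])

        def energy(y):
            dphi = np.diff(phi_of(y)) - self.kp * h
            return float(dphi @ dphi) / (2.0 * h)

        def grad(y):
            return H @ y + b

        def cons(y):
            phi = phi_of(y)
            return np.array([h * np.cos(phi).sum() - d,
                             h * np.sin(phi).sum()])

        def cons_jac(y):
            phi = phi_of(y)
            return np.stack([-h * np.sin(phi), h * np.cos(phi)])[:, 1:-1]

        s = np.linspace(0.0, 1.0, n_e)
        inits = []
        if k in self._warm and len(self._warm[k]) == m:
            inits.append(self._warm[k])
        if k == 0:
            a = 2.0 * np.sqrt(max(1.0 - d, 1e-9))
            inits.append((a * np.sin(2 * np.pi * s))[1:-1])
            inits.append((-a * np.sin(2 * np.pi * s))[1:-1])
        else:
            ramp = s * s * (3.0 - 2.0 * s)
            inits.append((end * ramp)[1:-1])

        for y0 in inits:
            y = np.asarray(y0, dtype=float).copy()
            lam = np.zeros(2)
            ok = False
            for it in range(200):
                g = grad(y)
                c = cons(y)
                J = cons_jac(y)
                r1 = g - J.T @ lam
                if np.abs(c).max() < 1e-11 and \
                        np.abs(r1).max() < 1e-8 * max(1.0, np.abs(g).max()):
                    ok = True
                    break
                phi = phi_of(y)
                dcurv = (-lam[0] * (-h * np.cos(phi)) -
                         lam[1] * (-h * np.sin(phi)))[1:-1]
                HL = H + np.diag(dcurv)
                KKT = np.zeros((m + 2, m + 2))
                KKT[:m, :m] = HL
                KKT[:m, m:] = -J.T
                KKT[m:, :m] = J
                rhs = np.concatenate([-r1, -c])
                try:
                    sol = np.linalg.solve(KKT, rhs)
                except np.linalg.LinAlgError:
                    break
                dy, dlam = sol[:m], sol[m:]
                # damped step on the KKT residual
                t = 1.0
                base = np.linalg.norm(r1) + np.linalg.norm(c) * 1e3
                for _ in range(30):
                    yt = y + t * dy
                    lt = lam + t * dlam
                    rt = (np.linalg.norm(grad(yt) - cons_jac(yt).T @ lt)
                          + np.linalg.norm(cons(yt)) * 1e3)
                    if rt < (1 - 1e-4 * t) * base or t < 1e-6:
                        break
                    t *= 0.5
                y = y + t * dy
                lam = lam + t * dlam
            if ok:
                self._warm[k] = y.copy()
                return energy(y), float(lam[0]), y
        raise RuntimeError(
            f"elastica BVP did not converge at d={d:.4g}, k={k}; "
            "try continuation from a nearer distance")

    def solve(self, d: float) -> tuple[float, float, np.ndarray]:
        """Return (energy, force, shape) at scaled end-to-end distance ``d``.

        Tries loop branches k = 0 .. ceil(total intrinsic turn / 2 pi)
        and returns the lowest-energy one.  Unit-B, unit-L scale:
        multiply force by ``B / L**2`` and energy by ``B / L``.
        """
        if d >= 1.0:
            raise ValueError("end-to-end distance must be below the contour "
                             "length (inextensible rod)")
        kmax = int(np.ceil(abs(self.kp) / (2.0 * np.pi)))
        sign = int(np.sign(self.kp)) or 1
        best = None
        for k in range(0, kmax + 1):
            try:
                E, lam, y = self._solve_branch(d, sign * k)
            except RuntimeError:
                continue
            if best is None or E < best[0]:
                best = (E, lam, y, sign * k)
        if best is None:
            raise RuntimeError(f"elastica BVP failed on all loop branches "
                               f"at d={d:.4g}")
        E, lam, y, k = best
        return E, lam, self._positions(y, k)

    def _positions(self, y: np.ndarray, k: int) -> np.ndarray:
        phi = np.concatenate([[0.0], y, [2.0 * np.pi * k]])
        x = np.zeros((self.n_e + 1, 2))
        x[1:, 0] = np.cumsum(self.h * np.cos(phi))
        x[1:, 1] = np.cumsum(self.h * np.sin(phi))
        return x


def elastica_shape_factor(kappa_hat: float, L: float, distances: np.ndarray,
                          n: int = 80) -> np.ndarray:
    """f(d) with F = B f(d): unit-modulus elastica forces (SI: 1/m²)."""
    solver = _ElasticaSolver(kappa_hat, L, n)
    ds = np.asarray(distances, dtype=float)
    order = np.argsort(ds)[::-1]          # continuation from near-straight
    out = np.empty_like(ds)
    for i in order:
        out[i] = solver.solve(float(ds[i]) / L)[1] / L ** 2
    return out


def elastica_force_displacement(B: float, kappa_hat: float, L: float,
                                distances, n: int = 80,
                                clip_slack: bool = True) -> np.ndarray:
    """Axial force (N) of the clamped-clamped elastica at each distance (m).

    A slack valve cannot push on the clamps, so compressive reactions
    (the buckled branch of a straight-ish rod) are reported as zero
    unless ``clip_slack`` is disabled.
    """
    F = B * elastica_shape_factor(kappa_hat, L, np.asarray(distances), n)
    return np.maximum(F, 0.0) if clip_slack else F


# ---------------------------------------------------------------------------
# extensometer-curve processing


def detect_rupture(curve: ExtensometerCurve, drop: float = 0.5,
                   floor: float = 0.15) -> int | None:
    """Index of the last sample before the rupture force collapse.

    Rupture means the force drops by more than ``drop`` of the running
    peak *to near zero* (below ``floor`` of the peak): a drop that
    settles at a substantial force is a coil loop popping out during
    uncurling, not the valve breaking.
    """
    F = curve.force_mN
    peak = np.maximum.accumulate(np.abs(F)) + 1e-30
    for i in range(1, len(F)):
        if F[i - 1] > 0 and (F[i - 1] - F[i]) > drop * peak[i - 1] \
                and F[i] < floor * peak[i - 1]:
            return i - 1
    return None


def correct_setup_compliance(raw: ExtensometerCurve,
                             min_window: int = 4,
                             r2_min: float = 0.995) -> ExtensometerCurve:
    """Remove setup travel from the displacement axis.

    The setup stiffness is the slope of the best straight-line fit over
    trailing windows of the pre-rupture curve (the post-straightening
    ramp); the corrected displacement is ``disp - F / k_setup`` and the
    curve is truncated at rupture.
    """
    rup = detect_rupture(raw)
    end = rup + 1 if rup is not None else len(raw.force_mN)
    x, F = raw.displacement_um[:end], raw.force_mN[:end]
    if end < min_window:
        raise ValueError("too few pre-rupture samples for a linear fit")
    best = None
    for k in range(min_window, end + 1):
        xs, Fs = x[end - k:end], F[end - k:end]
        A = np.vstack([xs, np.ones_like(xs)]).T
        coef, res_, *_ = np.linalg.lstsq(A, Fs, rcond=None)
        pred = A @ coef
        ss_res = float(np.sum((Fs - pred) ** 2))
        ss_tot = float(np.sum((Fs - Fs.mean()) ** 2)) + 1e-30
        r2 = 1.0 - ss_res / ss_tot
        if coef[0] > 0 and r2 >= r2_min:
            if best is None or k > best[0]:
                best = (k, coef[0])
    if best is None:
        raise ValueError("no linear pre-rupture region found (R² < "
                         f"{r2_min} on all candidate windows)")
    k_setup = best[1]
    corrected = x - F / k_setup
    return replace(raw, displacement_um=corrected, force_mN=F.copy(),
                   k_setup=k_setup, rupture_index=rup)


def fit_bending_stiffness(curve: ExtensometerCurve, kappa_hat: float,
                          L: float, d0: float | None = None,
                          fit_kappa: bool = False, n_boot: int = 200,
                          seed: int = 0, n_nodes: int = 80,
                          taut_fraction: float = 0.86) -> ElasticaFit:
    """Least-squares fit of the whole-valve bending stiffness.

    ``kappa_hat`` (1/m) and ``L`` (m) describe the excised valve; ``d0``
    (m) is the clamp separation at zero displacement (default: curve
    metadata).  Since ``F = B f(d)`` the fit of B is linear; an optional
    outer 1-D search refines ``kappa_hat``.  Confidence interval by
    residual bootstrap (seeded).  Samples beyond ``taut_fraction * L``
    are excluded: there the valve is essentially straight and the
    recorded force is dominated by the setup spring, not the elastica.
    """
    if d0 is None:
        if curve.d0_mm is None:
            raise ValueError("initial clamp separation d0 unknown")
        d0 = curve.d0_mm * 1e-3
    disp = curve.displacement_um * 1e-6
    F = curve.force_mN * 1e-3
    d = d0 + disp
    keep = d < taut_fraction * L
    d, F = d[keep], F[keep]
    if len(d) < 5:
        raise ValueError("fewer than 5 usable samples below the contour "
                         "length")

    def linear_B(kh):
        f = elastica_shape_factor(kh, L, d, n_nodes)
        denom = float(f @ f)
        if denom == 0:
            raise RuntimeError("degenerate shape factor")
        B = float(f @ F) / denom
        resid = F - B * f
        return B, f, resid

    if fit_kappa:
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(
            lambda kh: float(np.sum(linear_B(kh)[2] ** 2)),
            bracket=(0.5 * kappa_hat, kappa_hat, 1.5 * kappa_hat))
        kappa_hat = float(res.x)
    B, f, resid = linear_B(kappa_hat)

    rng = np.random.default_rng(seed)
    denom = float(f @ f)
    boots = []
    for _ in range(n_boot):
        Fb = B * f + rng.choice(resid, size=len(resid), replace=True)
        boots.append(float(f @ Fb) / denom)
    ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan,) * 2

    return ElasticaFit(B=B, kappa_hat=kappa_hat, L=L,
                       residual_norm=float(np.linalg.norm(resid)) * 1e3,
                       B_ci=ci)


# ---------------------------------------------------------------------------
# cross-scale inversion


def exocarp_from_valve(B_fit: float, valve: ValveModel,
                       gamma: float | None = None) -> tuple[float, float]:
    """Solve the trilayer stiffness for E_exocarp; return (E_exo, force).

    Finds the exocarp modulus at which the valve's effective bending
    stiffness (about its own neutral axis) equals ``B_fit`` (N·m²),
    keeping every other layer as given, then computes the exocarp
    pulling force ``F = E_exo * A_exo * gamma`` (N).
    """
    exo = valve.layers[-1]
    if gamma is None:
        gamma = -exo.g
    if gamma <= 0:
        raise ValueError("exocarp rest contraction must be positive")

    def bhat(E_exo):
        layers = valve.layers[:-1] + (replace(exo, E=E_exo),)
        return effective_bending_stiffness(replace(valve, layers=layers))

    lo = bhat(1e-12)
    if B_fit <= lo:
        raise ValueError(
            f"fitted stiffness {B_fit:.3e} N·m² does not exceed the "
            f"stiffness of the known layers ({lo:.3e}): exocarp modulus "
            "would be non-positive")
    hi = 1e12
    E_exo = brentq(lambda E: bhat(E) - B_fit, 1e-3, hi, xtol=1e-6,
                   rtol=1e-12)
    area = valve.w * exo.thickness
    return E_exo, E_exo * area * gamma
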