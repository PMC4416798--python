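"""Four-shell spherical head model, equivalent-dipole fitting and dipole-based
component rejection.

The forward problem — scalp potentials of a current dipole inside a set of
concentric conducting shells (brain, CSF, skull, scalp) — is solved with the
classical spherical-harmonic series.  For each harmonic degree ``n`` the
potential in shell :math:`j` is :math:`A_j r^n + B_j r^{-(n+1)}` times the
angular term; the coefficients follow from continuity of potential and radial
current at each interface and a zero-current condition at the scalp surface.
Because the boundary system is linear in the source strength, a single
transfer coefficient per degree can be precomputed per head model, after
which one forward evaluation is a short vectorised series sum.

The inverse problem (one equivalent dipole per independent-component scalp
map) is a 3-parameter search over the source location; at every candidate
location the dipole moment is the linear least-squares solution against the
three unit-moment forward fields.

Coordinate frame: +x anterior, +y left, +z superior, origin at the sphere
centre, lengths in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy import optimize, signal, stats

logger = logging.getLogger(__name__)

#: frontal channels used by the eye-component detector
FRONTAL_LABELS = ("Fp1", "Fpz", "Fp2", "AF7", "AF8")


class DomainError(ValueError):
    """Source location outside the physically valid domain."""


class ConvergenceError(RuntimeError):
    """Spherical-harmonic series did not converge within ``series_terms``."""


@dataclass(frozen=True)
class HeadModel:
    """Concentric 4-shell spherical volume conductor.

    Parameters
    ----------
    shell_radii
        Outer radii (mm) of brain, CSF, skull and scalp shells, increasing.
    shell_conductivities
        Conductivities (S/m) of the four shells, innermost first.
    series_terms
        Truncation of the Legendre expansion.  Terms are cut early once a
        degree contributes less than ``series_rtol`` relative to the running
        sum; if the last computed degree still exceeds the tolerance a
        :class:`ConvergenceError` is raised.
    """

    shell_radii: tuple[float, float, float, float] = (71.0, 72.0, 79.0, 85.0)
    shell_conductivities: tuple[float, float, float, float] = (0.33, 1.0, 0.0042, 0.33)
    series_terms: int = 100
    series_rtol: float = 1e-12

    def __post_init__(self) -> None:
        r = np.asarray(self.shell_radii, float)
        s = np.asarray(self.shell_conductivities, float)
        if r.shape != (4,) or s.shape != (4,):
            raise ValueError("need exactly four shells")
        if not np.all(np.diff(r) > 0):
            raise ValueError("shell radii must be strictly increasing")
        if not np.all(s > 0):
            raise ValueError("conductivities must be strictly positive")
        if self.series_terms < 20:
            raise ValueError("series_terms must be >= 20")

    @property
    def brain_radius(self) -> float:
        return float(self.shell_radii[0])

    @property
    def scalp_radius(self) -> float:
        return float(self.shell_radii[3])


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set on the scalp sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        object.__setattr__(self, "positions", pos)
        if len(self.labels) != 64 or pos.shape != (64, 3):
            raise ValueError("montage must contain exactly 64 electrodes")
        if len(set(self.labels)) != 64:
            raise ValueError("electrode labels must be unique")
        radii = np.linalg.norm(pos, axis=1)
        if not np.allclose(radii, radii[0], rtol=1e-9):
            raise ValueError("all electrodes must lie on the scalp sphere")

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.positions[0]))

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def from_tsv(cls, path) -> "Montage":
        labels, rows = [], []
        with open(path) as fh:
            header = fh.readline().split()
            if header[:4] != ["label", "x", "y", "z"]:
                raise ValueError("montage TSV must have columns label, x, y, z")
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:4]])
        return cls(tuple(labels), np.array(rows))

    @classmethod
    def default(cls) -> "Montage":
        """64-channel spherical montage in the standard Biosemi channel order."""
        ref = resources.files("gaitdecode.data") / "biosemi64_sphere.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class Dipole:
    """Point current source: location in mm (head frame), moment in nA·m."""

    location: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "location", np.asarray(self.location, float))
        object.__setattr__(self, "moment", np.asarray(self.moment, float))
        if self.location.shape != (3,) or self.moment.shape != (3,):
            raise ValueError("location and moment must be 3-vectors")


@dataclass(frozen=True)
class DipoleFit:
    dipole: Dipole
    residual_variance: float
    radial_fraction: float
    converged: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_variance <= 1.0 + 1e-12:
            raise ValueError("residual_variance must lie in [0, 1]")
        if self.radial_fraction < 0:
            raise ValueError("radial_fraction must be non-negative")


# ---------------------------------------------------------------------------
# forward solution


@lru_cache(maxsize=32)
def _transfer_coefficients(radii: tuple, sigmas: tuple, n_max: int) -> np.ndarray:
    """Per-degree transfer coefficient t_n of the outermost regular term.

    Radii are normalised by the scalp radius.  For each degree the 7 unknown
    expansion coefficients (A1, A2, B2, A3, B3, A4, B4) are solved from the
    interface/boundary conditions with the source singular term set to unit
    strength; ``t_n`` is the resulting A4.
    """
    rho = np.asarray(radii, float) / radii[-1]
    sig = np.asarray(sigmas, float)
    t = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        M = np.zeros((7, 7))
        rhs = np.zeros(7)
        # unknown order: A1, A2, B2, A3, B3, A4, B4
        cols = {("A", 1): 0, ("A", 2): 1, ("B", 2): 2, ("A", 3): 3,
                ("B", 3): 4, ("A", 4): 5, ("B", 4): 6}
        row = 0
        for j in (1, 2, 3):  # interface between shell j and j+1 at rho[j-1]
            r = rho[j - 1]
            rn, rm = r ** n, r ** -(n + 1)
            # potential continuity
            M[row, cols[("A", j)]] += rn
            if j > 1:
                M[row, cols[("B", j)]] += rm
            M[row, cols[("A", j + 1)]] -= rn
            M[row, cols[("B", j + 1)]] -= rm
            if j == 1:
                rhs[row] = -rm  # source term B1 = 1 moves to the RHS
            row += 1
            # radial current continuity
            dn, dm = n * r ** (n - 1), -(n + 1) * r ** -(n + 2)
            M[row, cols[("A", j)]] += sig[j - 1] * dn
            if j > 1:
                M[row, cols[("B", j)]] += sig[j - 1] * dm
            M[row, cols[("A", j + 1)]] -= sig[j] * dn
            M[row, cols[("B", j + 1)]] -= sig[j] * dm
            if j == 1:
                rhs[row] = -sig[0] * dm
            row += 1
        # insulating outer boundary at rho = 1
        M[row, cols[("A", 4)]] = n
        M[row, cols[("B", 4)]] = -(n + 1)
        x = np.linalg.solve(M, rhs)
        t[n] = x[cols[("A", 4)]]
    return t


def _legendre_terms(c: np.ndarray, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(c) and P'_n(c) for n = 0..n_max, vectorised over electrodes."""
    P = np.zeros((n_max + 1, c.size))
    dP = np.zeros_like(P)
    P[0] = 1.0
    if n_max >= 1:
        P[1] = c
        dP[1] = 1.0
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * c * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    return P, dP


def _series_depth(brel: float, model: HeadModel) -> int:
    """Number of degrees needed for the geometric series factor to reach rtol."""
    if brel < 1e-12:
        return 2
    needed = 1 + int(np.ceil(np.log(model.series_rtol) / np.log(brel)))
    if needed > model.series_terms:
        if brel ** (model.series_terms - 1) > 1e-6:
            raise ConvergenceError(
                f"series not converged after {model.series_terms} terms for a "
                f"source at {brel:.3f} of the scalp radius")
        needed = model.series_terms
    return max(needed, 10)


def dipole_gain(location: np.ndarray, montage: Montage, model: HeadModel) -> np.ndarray:
    """64×3 average-referenced gain matrix (µV per nA·m of moment).

    Column ``j`` is the forward map of a unit dipole moment along axis ``j``
    at ``location``; ``forward_potentials`` is this matrix applied to the
    moment vector.
    """
    R = model.scalp_radius
    if abs(montage.radius - R) > 1e-6 * R:
        raise ValueError("montage radius does not match the scalp shell radius")
    loc = np.asarray(location, float)
    b = float(np.linalg.norm(loc))
    if b >= model.brain_radius:
        raise DomainError("dipole must lie strictly inside the brain shell")

    t = _transfer_coefficients(tuple(model.shell_radii),
                               tuple(model.shell_conductivities),
                               model.series_terms)
    sigma1 = model.shell_conductivities[0]
    R_m = R * 1e-3
    # nA·m moments, µV output
    scale = 1e-3 / (4.0 * np.pi * sigma1 * R_m ** 2)
    e_hat = montage.positions / R

    if b < 1e-9:
        # only degree n = 1 survives; the map of unit moment e_j is ∝ ê·e_j
        G = t[1] * 1.5 * scale * e_hat
        return G - G.mean(axis=0)

    q_hat = loc / b
    c = np.clip(e_hat @ q_hat, -1.0, 1.0)
    brel = b / R
    N = _series_depth(brel, model)
    P, dP = _legendre_terms(c, N)
    n = np.arange(1, N + 1)
    coef = t[1:N + 1] * (2 * n + 1) / (n + 1) * brel ** (n - 1)
    S1 = (coef * n) @ P[1:]    # Σ coef_n · n · P_n(c)  per electrode
    S2 = coef @ dP[1:]         # Σ coef_n · P'_n(c)     per electrode
    G = scale * (np.outer(S1 - c * S2, q_hat) + S2[:, None] * e_hat)
    return G - G.mean(axis=0)


def forward_potentials(dipole: Dipole, montage: Montage, model: HeadModel) -> np.ndarray:
    """Average-referenced scalp potentials (µV) of a dipole at the montage.

    The result is linear in the dipole moment (nA·m).
    """
    return dipole_gain(dipole.location, montage, model) @ dipole.moment


def homogeneous_sphere_potentials(dipole: Dipole, montage: Montage,
                                  sigma: float, radius: float) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous sphere (µV).

    Independent of the shell series: derived from generating-function
    identities for the Legendre sums, giving an expression in elementary
    functions only.  Average-referenced for comparison with
    :func:`forward_potentials`.
    """
    loc = dipole.location
    b = float(np.linalg.norm(loc))
    if b >= radius:
        raise DomainError("dipole must lie inside the sphere")
    if b < 1e-9:
        raise ValueError("closed form is singular at the origin; offset the dipole")
    R_m = radius * 1e-3
    m_si = dipole.moment * 1e-9
    a = b / radius
    q_hat = loc / b
    e_hat = montage.positions / radius
    c = np.clip(e_hat @ q_hat, -1.0, 1.0)
    m_r = float(m_si @ q_hat)
    m_e = e_hat @ m_si
    D = np.sqrt(1.0 - 2.0 * a * c + a * a)

    # Surface potential is (1/4πσR²) Σ a^{n-1} (2n+1)/n [n m_r P_n + m_t s P'_n];
    # the two Legendre sums reduce to elementary functions:
    # G1 = Σ a^{n-1} (2n+1) P_n(c)
    G1 = 2.0 * (c - a) / D ** 3 + (1.0 / D - 1.0) / a
    # G2 = Σ a^{n-1} (2n+1)/n P'_n(c)
    G2 = 2.0 / D ** 3 + (D + 1.0) / (D * (1.0 - a * c + D))

    v = (m_r * G1 + (m_e - c * m_r) * G2) / (4.0 * np.pi * sigma * R_m ** 2)
    v *= 1e6
    return v - v.mean()


# ---------------------------------------------------------------------------
# inverse solution


def _map_residual_variance(scalp_map: np.ndarray, loc: np.ndarray,
                           montage: Montage, model: HeadModel
                           ) -> tuple[float, np.ndarray]:
    G = dipole_gain(loc, montage, model)
    m, *_ = np.linalg.lstsq(G, scalp_map, rcond=None)
    resid = scalp_map - G @ m
    denom = float(np.sum((scalp_map - scalp_map.mean()) ** 2))
    return float(np.sum(resid ** 2) / denom), m


def fit_single_dipole(scalp_map: np.ndarray, montage: Montage, model: HeadModel,
                      n_restarts: int = 8, seed: int | None = 0) -> DipoleFit:
    """Fit one equivalent current dipole to a scalp map.

    Multi-start Nelder–Mead over the source location; the moment is solved by
    least squares at every candidate.  Residual variance is the fraction of
    (mean-removed) map variance left unexplained; the best restart wins.
    """
    scalp_map = np.asarray(scalp_map, float)
    if scalp_map.shape != (64,):
        raise ValueError("scalp map must have 64 entries")
    if np.allclose(scalp_map, 0.0):
        raise ValueError("cannot fit a dipole to an all-zero scalp map")
    scalp_map = scalp_map - scalp_map.mean()

    limit = 0.97 * model.brain_radius
    rng = np.random.default_rng(seed)
    # coarser series truncation during the search; the returned fit is
    # re-evaluated with the full model
    search_model = HeadModel(shell_radii=model.shell_radii,
                             shell_conductivities=model.shell_conductivities,
                             series_terms=model.series_terms,
                             series_rtol=max(model.series_rtol, 1e-9))

    def objective(loc):
        r = np.linalg.norm(loc)
        if r >= limit:
            return 1.0 + (r - limit) / model.brain_radius
        rv, _ = _map_residual_variance(scalp_map, loc, montage, search_model)
        return rv

    best = None
    start_radius = 0.6 * model.scalp_radius
    for _ in range(max(1, n_restarts)):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        x0 = u * min(start_radius, 0.85 * limit)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-2, "fatol": 1e-8,
                                         "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res

    loc = best.x
    ok = bool(best.success) and np.linalg.norm(loc) < limit
    if not ok:
        rv = 1.0
        moment = np.zeros(3)
        loc = np.clip(loc, -limit, limit)
        if np.linalg.norm(loc) >= limit:
            loc = loc * (0.99 * limit / np.linalg.norm(loc))
    else:
        rv, moment = _map_residual_variance(scalp_map, loc, montage, model)
        rv = float(min(max(rv, 0.0), 1.0))
    return DipoleFit(dipole=Dipole(loc, moment),
                     residual_variance=rv,
                     radial_fraction=float(np.linalg.norm(loc) / model.scalp_radius),
                     converged=ok)


# ---------------------------------------------------------------------------
# component rejection heuristics


def reject_components_by_dipole(fits: list[DipoleFit],
                                rv_max: float = 0.10,
                                radial_max: float = 0.70,
                                z_min: float = 0.0) -> tuple[np.ndarray, list[list[str]]]:
    """Dipole-based rejection mask (True = keep) with per-component reasons.

    A component is rejected only when strictly beyond a threshold: residual
    variance above ``rv_max``, radial fraction above ``radial_max`` (outside
    the head / close to the skull), or dipole z below ``z_min``
    (cerebellum/neck).
    """
    keep = np.ones(len(fits), bool)
    reasons: list[list[str]] = []
    for i, fit in enumerate(fits):
        why = []
        if fit.residual_variance > rv_max:
            why.append("residual_variance")
        if fit.radial_fraction > radial_max:
            why.append("radial_fraction")
        if fit.dipole.location[2] < z_min:
            why.append("low_z")
        if why:
            keep[i] = False
        reasons.append(why)
    return keep, reasons


def detect_eye_components(scalp_maps: np.ndarray, activations: np.ndarray,
                          montage: Montage, fs: float,
                          frontal_factor: float = 2.0,
                          lowfreq_fraction: float = 0.55,
                          kurtosis_max: float = 10.0) -> np.ndarray:
    """Flag ocular components (True = eye artifact).

    A component is ocular when its scalp map is frontally dominated (mean
    absolute weight over Fp1/Fpz/Fp2/AF7/AF8 exceeds the mean elsewhere by
    ``frontal_factor``) *and* its activation is blink-like: either most of the
    power below 4 Hz (fraction above ``lowfreq_fraction``) or a spiky
    amplitude distribution (excess kurtosis above ``kurtosis_max``).
    """
    scalp_maps = np.atleast_2d(np.asarray(scalp_maps, float))
    activations = np.atleast_2d(np.asarray(activations, float))
    try:
        fidx = [montage.index(lbl) for lbl in FRONTAL_LABELS]
    except ValueError as exc:
        raise ValueError("montage lacks the frontal labels needed for eye "
                         "detection") from exc
    rest = [i for i in range(64) if i not in fidx]
    flagged = np.zeros(scalp_maps.shape[0], bool)
    for i, (w, act) in enumerate(zip(scalp_maps, activations)):
        if np.std(act) == 0:
            logger.warning("component %d has zero-variance activation; "
                           "skipping eye detection", i)
            continue
        frontal = np.mean(np.abs(w[fidx]))
        elsewhere = np.mean(np.abs(w[rest]))
        if frontal <= frontal_factor * max(elsewhere, 1e-30):
            continue
        nper = min(act.size, int(4 * fs))
        freqs, psd = signal.welch(act, fs=fs, nperseg=nper)
        low = float(psd[freqs < 4.0].sum() / max(psd.sum(), 1e-30))
        kurt = float(stats.kurtosis(act))
        if low > lowfreq_fraction or kurt > kurtosis_max:
            flagged[i] = True
    return flagged
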