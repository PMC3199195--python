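"""Repressilator vector fields, parameters, and analytic Jacobians.

The repressilator is a three-gene ring oscillator (lacI -> tetR -> cI ->
lacI) in which each protein represses transcription of the next gene.
Two repressilators living in adjacent cells are coupled by first-order
bidirectional diffusion of the TetR protein; the diffusion rate ``diff``
is the coupling strength.

State ordering convention used throughout the package::

    single cell : (lp, tp, cp, lr, tr, cr)
    coupled pair: cell A block followed by cell B block (12 components)

where ``lp, tp, cp`` are the LacI, TetR and cI protein concentrations and
``lr, tr, cr`` the corresponding mRNA concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SPECIES",
    "COUPLED_SPECIES",
    "RepressilatorParams",
    "CouplingParams",
    "REFERENCE_CYCLE_POINT",
    "single_rhs",
    "coupled_rhs",
    "single_jacobian",
    "coupled_jacobian",
]

#: names of the six state variables of one cell, in state-vector order
SPECIES = ("lp", "tp", "cp", "lr", "tr", "cr")

#: names of the twelve state variables of the coupled pair
COUPLED_SPECIES = tuple(f"{s}_a" for s in SPECIES) + tuple(f"{s}_b" for s in SPECIES)


@dataclass(frozen=True)
class RepressilatorParams:
    """Kinetic constants of one cell's gene circuit.

    Defaults are the published fit for the TetR-coupled repressilator:
    transcription is leaky (``alpha0``) and repressed through a Hill term
    with threshold ``km`` and exponent ``n``; each mRNA is removed by two
    first-order terms (rates ``k_*r`` and ``k_*r2``) and produces its
    protein at rate ``k_*r``; proteins degrade at rates ``k_*p``.

    ``hill_exponent_on_repressor`` switches between the standard Hill
    repression form ``km**n / (km**n + x**n)`` (default) and the variant
    with a linear repressor in the denominator, ``km**n / (km**n + x)``.
    The latter does not sustain oscillations at the default constants and
    is provided for sensitivity checks only.
    """

    alpha0: float = 0.03
    alpha: float = 29.97
    km: float = 40.0
    n: int = 3
    k_lp: float = 0.069
    k_tp: float = 0.069
    k_cp: float = 0.069
    k_lr: float = 6.93
    k_tr: float = 6.93
    k_cr: float = 6.93
    k_lr2: float = 0.347
    k_tr2: float = 0.347
    k_cr2: float = 0.347
    hill_exponent_on_repressor: bool = True

    def __post_init__(self) -> None:
        rates = (
            self.alpha0, self.alpha, self.km,
            self.k_lp, self.k_tp, self.k_cp,
            self.k_lr, self.k_tr, self.k_cr,
            self.k_lr2, self.k_tr2, self.k_cr2,
        )
        if any(r < 0 for r in rates):
            raise ValueError("all rate constants and km must be nonnegative")
        if self.n < 1:
            raise ValueError("Hill exponent n must be >= 1")

    def with_degradation_scale(self, s: float) -> "RepressilatorParams":
        """Return a copy with the three protein degradation rates scaled by ``s``.

        Uniform scaling of ``k_lp, k_tp, k_cp`` is the one-parameter handle
        used to tune the free-running oscillation frequency.
        """
        if s <= 0:
            raise ValueError("degradation scale must be positive")
        return replace(
            self, k_lp=s * self.k_lp, k_tp=s * self.k_tp, k_cp=s * self.k_cp
        )

    def hill(self, x: float | np.ndarray) -> float | np.ndarray:
        """Repressed transcription rate alpha0 + alpha * km^n / (km^n + x^n)."""
        kmn = self.km ** self.n
        rep = np.asarray(x, dtype=float) ** self.n if self.hill_exponent_on_repressor else x
        return self.alpha0 + self.alpha * kmn / (kmn + rep)

    def hill_prime(self, x: float) -> float:
        """d/dx of the repressed transcription rate."""
        kmn = self.km ** self.n
        if self.hill_exponent_on_repressor:
            xn = x ** self.n
            return -self.alpha * self.n * kmn * x ** (self.n - 1) / (kmn + xn) ** 2
        return -self.alpha * kmn / (kmn + x) ** 2


@dataclass(frozen=True)
class CouplingParams:
    """Bidirectional TetR diffusion rate between the two cells.

    The study's relevant range is ``diff`` in [0.01, 0.13] (weak to strong
    coupling); ``diff = 0`` decouples the cells exactly.
    """

    diff: float = 0.0

    def __post_init__(self) -> None:
        if self.diff < 0:
            raise ValueError("diffusion rate must be nonnegative")


#: published point on the limit cycle used as the standard starting state
#: (lp, tp, cp, lr, tr, cr)
REFERENCE_CYCLE_POINT = np.array([36.263, 166.685, 64.26, 0.819, 2.388, 0.068])


def _check_state(y: np.ndarray, size: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (size,):
        raise ValueError(f"state must have shape ({size},), got {y.shape}")
    if np.any(y < 0):
        raise ValueError("concentrations must be nonnegative")
    return y


def single_rhs(
    y: np.ndarray,
    p: RepressilatorParams,
    diff: float = 0.0,
    tp_external: float = 0.0,
) -> np.ndarray:
    """Time derivative of one repressilator cell.

    ``diff`` and ``tp_external`` add the TetR exchange term
    ``-diff*tp + diff*tp_external`` to the ``tp`` equation; with the
    defaults the cell is uncoupled.
    """
    lp, tp, cp, lr, tr, cr = _check_state(y, 6)
    return np.array(
        [
            p.k_lr * lr - p.k_lp * lp,
            p.k_tr * tr - p.k_tp * tp - diff * tp + diff * tp_external,
            p.k_cr * cr - p.k_cp * cp,
            p.hill(cp) - (p.k_lr + p.k_lr2) * lr,
            p.hill(lp) - (p.k_tr + p.k_tr2) * tr,
            p.hill(tp) - (p.k_cr + p.k_cr2) * cr,
        ]
    )


def coupled_rhs(
    y: np.ndarray,
    p_a: RepressilatorParams,
    p_b: RepressilatorParams,
    c: CouplingParams,
) -> np.ndarray:
    """Time derivative of the two-cell system (12 components).

    Each cell follows :func:`single_rhs` with the partner cell's TetR
    concentration as ``tp_external``; the total TetR exchange is
    antisymmetric, so the sum of the two ``tp`` derivatives is independent
    of ``diff``.
    """
    y = _check_state(y, 12)
    a, b = y[:6], y[6:]
    da = single_rhs(a, p_a, diff=c.diff, tp_external=b[1])
    db = single_rhs(b, p_b, diff=c.diff, tp_external=a[1])
    return np.concatenate([da, db])


def single_jacobian(
    y: np.ndarray, p: RepressilatorParams, diff: float = 0.0
) -> np.ndarray:
    """Analytic 6x6 Jacobian of :func:`single_rhs` w.r.t. the cell's own state."""
    lp, tp, cp, lr, tr, cr = _check_state(y, 6)
    J = np.zeros((6, 6))
    # protein rows
    J[0, 0] = -p.k_lp
    J[0, 3] = p.k_lr
    J[1, 1] = -p.k_tp - diff
    J[1, 4] = p.k_tr
    J[2, 2] = -p.k_cp
    J[2, 5] = p.k_cr
    # mRNA rows: repression cycle cp -| lr, lp -| tr, tp -| cr
    J[3, 2] = p.hill_prime(cp)
    J[3, 3] = -(p.k_lr + p.k_lr2)
    J[4, 0] = p.hill_prime(lp)
    J[4, 4] = -(p.k_tr + p.k_tr2)
    J[5, 1] = p.hill_prime(tp)
    J[5, 5] = -(p.k_cr + p.k_cr2)
    return J


def make_single_rhs(p: RepressilatorParams):
    """Validation-free single-cell RHS closure for the integrator hot path.

    Semantically identical to :func:`single_rhs` at ``diff = 0`` except that
    negative round-off excursions are clipped to zero instead of rejected.
    """
    kmn = p.km ** p.n
    n = p.n
    a0, a = p.alpha0, p.alpha
    klp, ktp, kcp = p.k_lp, p.k_tp, p.k_cp
    klr, ktr, kcr = p.k_lr, p.k_tr, p.k_cr
    rl, rt, rc = p.k_lr + p.k_lr2, p.k_tr + p.k_tr2, p.k_cr + p.k_cr2
    power = p.hill_exponent_on_repressor

    def rhs(t, y):
        lp = y[0] if y[0] > 0 else 0.0
        tp = y[1] if y[1] > 0 else 0.0
        cp = y[2] if y[2] > 0 else 0.0
        lr = y[3] if y[3] > 0 else 0.0
        tr = y[4] if y[4] > 0 else 0.0
        cr = y[5] if y[5] > 0 else 0.0
        if power:
            h_cp = a0 + a * kmn / (kmn + cp**n)
            h_lp = a0 + a * kmn / (kmn + lp**n)
            h_tp = a0 + a * kmn / (kmn + tp**n)
        else:
            h_cp = a0 + a * kmn / (kmn + cp)
            h_lp = a0 + a * kmn / (kmn + lp)
            h_tp = a0 + a * kmn / (kmn + tp)
        return (
            klr * lr - klp * lp,
            ktr * tr - ktp * tp,
            kcr * cr - kcp * cp,
            h_cp - rl * lr,
            h_lp - rt * tr,
            h_tp - rc * cr,
        )

    return rhs


def make_coupled_rhs(
    p_a: RepressilatorParams, p_b: RepressilatorParams, c: CouplingParams
):
    """Validation-free coupled-pair RHS closure (see :func:`make_single_rhs`)."""
    rhs_a = make_single_rhs(p_a)
    rhs_b = make_single_rhs(p_b)
    diff = c.diff

    def rhs(t, y):
        da = rhs_a(t, y[:6])
        db = rhs_b(t, y[6:])
        tp_a = y[1] if y[1] > 0 else 0.0
        tp_b = y[7] if y[7] > 0 else 0.0
        ex = diff * (tp_b - tp_a)
        return (
            da[0], da[1] + ex, da[2], da[3], da[4], da[5],
            db[0], db[1] - ex, db[2], db[3], db[4], db[5],
        )

    return rhs


def coupled_jacobian(
    y: np.ndarray,
    p_a: RepressilatorParams,
    p_b: RepressilatorParams,
    c: CouplingParams,
) -> np.ndarray:
    """Analytic 12x12 Jacobian of :func:`coupled_rhs`.

    Block-diagonal at ``diff = 0``; the only cross-cell entries are the
    ``+diff`` couplings between the two ``tp`` equations.
    """
    y = _check_state(y, 12)
    a, b = y[:6], y[6:]
    J = np.zeros((12, 12))
    J[:6, :6] = single_jacobian(a, p_a, diff=c.diff)
    J[6:, 6:] = single_jacobian(b, p_b, diff=c.diff)
    J[1, 7] = c.diff  # d(tp_a')/d(tp_b)
    J[7, 1] = c.diff  # d(tp_b')/d(tp_a)
    return J
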