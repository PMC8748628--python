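"""Two-locus haploid dynamics of male mate choice with post-pairing trade-offs.

A deterministic population-genetic recursion for one preference locus P
(expressed in males) and one trait locus T (expressed in females), in a
haploid population with non-overlapping generations.  P2 males court T2
females more vigorously pre-pairing and, once socially paired with an
unpreferred T1 female, shift post-pairing effort toward extra-pair
copulations (EPCs) at the expense of either

* mate guarding  -- their share of within-pair paternity drops from
  ``theta`` to ``theta - delta_theta`` (``Tradeoff.GUARDING``), or
* paternal care  -- the pair's surviving-offspring output drops from
  ``1 + b`` to ``1 + b*(1 - delta)`` (``Tradeoff.CARE``),

while their EPC-seeking effort rises from ``e`` to ``e + delta_e``.
Optional viability costs ``s_f`` (on T2 females) and ``s_m`` (on P2 males)
act before pairing.

The module is laid out in the order one generation runs:

1.  parameters and population state;
2.  the one-generation recursion (viability selection, courtship, pairing,
    paternity / effort / fecundity tables, extra-pair siring shares,
    offspring accounting, recombination);
3.  equilibrium analysis (iteration, the analytic polymorphism conditions,
    edge equilibria, numerical Jacobian stability, basin sweeps, region maps);
4.  a finite-population individual-based Monte-Carlo oracle;
5.  configuration-file / CSV plumbing and the figure-data protocols.

Genotype order is fixed globally as (P1T1, P1T2, P2T1, P2T2); matrices are
oriented rows = female genotype i, columns = male genotype j.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "T2_FEMALE",
    "P2_MALE",
    "Tradeoff",
    "ModelParams",
    "Summary",
    "state_from_freqs",
    "summarize",
    "validate_state",
    "viability_select_females",
    "viability_select_males",
    "courtship_matrix",
    "pairing_matrix",
    "paternity_matrix",
    "epc_effort_matrix",
    "fecundity_matrix",
    "siring_shares",
    "MatingTables",
    "mating_tables",
    "OffspringTables",
    "offspring_tables",
    "transmission_tensor",
    "transmit",
    "step",
    "Trajectory",
    "iterate_to_equilibrium",
    "condition_guarding",
    "condition_care",
    "condition_costly_trait",
    "condition_internal_costly",
    "condition_both_costly",
    "condition_flags",
    "edge_equilibrium_p2",
    "Stability",
    "EquilibriumReport",
    "classify_stability",
    "basin_sweep",
    "region_map",
    "ABMConfig",
    "simulate_abm",
    "abm_one_generation",
    "read_config",
    "params_from_mapping",
    "trajectory_to_dataframe",
    "figures_protocol",
]

logger = logging.getLogger("matechoice")

#: genotype labels in the fixed global index order
GENOTYPES = ("P1T1", "P1T2", "P2T1", "P2T2")

#: boolean masks over the genotype index: carriers of the female trait allele
#: T2 (indices 1, 3) and of the male preference allele P2 (indices 2, 3)
T2_FEMALE = np.array([False, True, False, True])
P2_MALE = np.array([False, False, True, True])

_SIMPLEX_TOL = 1e-12


class Tradeoff(enum.Enum):
    """Which post-pairing reallocation choosy males make when paired with T1."""

    GUARDING = "guarding"
    CARE = "care"


# ---------------------------------------------------------------------------
# Parameters and population state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """All evolutionary and behavioral parameters of the model.

    Parameters
    ----------
    a
        Strength of male preference: P2 males court T2 females with weight
        ``1 + a`` relative to T1 females.  ``a >= 0``.
    theta
        Proportion of within-pair offspring under full guarding, in (0, 1].
        Equals ``1 - alpha*beta`` of the underlying EPC process; alpha and
        beta never enter separately.
    delta_theta
        Paternity reduction suffered by P2 males paired with T1 females
        (guarding trade-off only).  Requires ``theta - delta_theta > 0``.
    e
        Baseline EPC-seeking effort of every male; positive.
    delta_e
        Additional EPC effort of P2 males paired with T1 females; >= 0.
    b
        Relative effect of male care on offspring survival (care trade-off);
        female care is normalized to 1, so a fully caring pair rears
        ``1 + b`` offspring.
    delta
        Proportional care reduction by P2 males paired with T1 females, in
        [0, 1] (care trade-off only).
    s_f, s_m
        Viability cost of the T2 trait in females / the P2 preference in
        males, each in [0, 1); 0 disables the cost.
    r
        Recombination rate between the P and T loci, in [0, 0.5];
        free recombination (0.5) by default.
    tradeoff
        Which post-pairing trade-off is active.
    """

    a: float = 1.0
    theta: float = 0.8
    delta_theta: float = 0.0
    e: float = 0.8
    delta_e: float = 0.0
    b: float = 0.0
    delta: float = 0.0
    s_f: float = 0.0
    s_m: float = 0.0
    r: float = 0.5
    tradeoff: Tradeoff = Tradeoff.GUARDING

    def __post_init__(self) -> None:
        if isinstance(self.tradeoff, str):
            object.__setattr__(self, "tradeoff", Tradeoff(self.tradeoff.lower()))
        for name in ("a", "theta", "delta_theta", "e", "delta_e", "b",
                     "delta", "s_f", "s_m", "r"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if not 0 < self.theta <= 1:
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if self.delta_theta < 0:
            raise ValueError(f"delta_theta must be >= 0, got {self.delta_theta}")
        if self.tradeoff is Tradeoff.GUARDING and self.theta - self.delta_theta <= 0:
            raise ValueError(
                "guarding trade-off requires theta - delta_theta > 0 "
                f"(theta={self.theta}, delta_theta={self.delta_theta})")
        if self.e <= 0:
            raise ValueError(f"e must be > 0, got {self.e}")
        if self.delta_e < 0:
            raise ValueError(f"delta_e must be >= 0, got {self.delta_e}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if not 0 <= self.delta <= 1:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if not 0 <= self.s_f < 1:
            raise ValueError(f"s_f must be in [0, 1), got {self.s_f}")
        if not 0 <= self.s_m < 1:
            raise ValueError(f"s_m must be in [0, 1), got {self.s_m}")
        if not 0 <= self.r <= 0.5:
            raise ValueError(f"r must be in [0, 0.5], got {self.r}")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["tradeoff"] = self.tradeoff.value
        return d


class Summary(NamedTuple):
    """Allele frequencies and linkage disequilibrium of a population state."""

    p2: float  #: frequency of the male-preference allele P2 (= x3 + x4)
    t2: float  #: frequency of the female-trait allele T2 (= x2 + x4)
    D: float   #: linkage disequilibrium x1*x4 - x2*x3


def validate_state(x: np.ndarray) -> np.ndarray:
    """Check that ``x`` is a genotype-frequency 4-vector on the simplex."""
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"state must be a 4-vector, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite entries")
    if np.any(x < -_SIMPLEX_TOL) or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"state is not on the frequency simplex: {x}")
    return np.clip(x, 0.0, None) / np.clip(x, 0.0, None).sum()


def state_from_freqs(p2: float, t2: float, D: float = 0.0) -> np.ndarray:
    """Build the genotype 4-vector with allele frequencies ``p2, t2`` and LD ``D``.

    Inverse of :func:`summarize`: ``x4 = D + p2*t2`` and the rest follow.
    """
    x4 = D + p2 * t2
    x3 = p2 - x4
    x2 = t2 - x4
    x1 = 1.0 - x2 - x3 - x4
    return validate_state(np.array([x1, x2, x3, x4]))


def summarize(x: np.ndarray) -> Summary:
    """Allele frequencies p2, t2 and linkage disequilibrium D of state ``x``."""
    x = np.asarray(x, dtype=float)
    return Summary(p2=float(x[2] + x[3]), t2=float(x[1] + x[3]),
                   D=float(x[0] * x[3] - x[1] * x[2]))


# ---------------------------------------------------------------------------
# One-generation recursion, stage by stage
# ---------------------------------------------------------------------------


def _viability_select(x: np.ndarray, s: float, carrier: np.ndarray) -> np.ndarray:
    if not (math.isfinite(s) and 0 <= s < 1):
        raise ValueError(f"selection coefficient must be in [0, 1), got {s}")
    x = np.asarray(x, dtype=float)
    if x.shape != (4,) or not np.all(np.isfinite(x)):
        raise ValueError("viability selection requires a finite 4-vector")
    w = np.where(carrier, 1.0 - s, 1.0) * x
    return w / w.sum()


def viability_select_females(x: np.ndarray, s_f: float) -> np.ndarray:
    """Female pool after viability selection against the T2 trait.

    T2 carriers are down-weighted by ``1 - s_f`` and the vector renormalized
    by the mean female viability ``1 - s_f * t2``.
    """
    return _viability_select(x, s_f, T2_FEMALE)


def viability_select_males(x: np.ndarray, s_m: float) -> np.ndarray:
    """Male pool after viability selection against the P2 preference."""
    return _viability_select(x, s_m, P2_MALE)


def _preference_weight(a: float) -> np.ndarray:
    # (1 + d*a) with d = 1 iff female carries T2 AND male carries P2
    return 1.0 + a * np.outer(T2_FEMALE, P2_MALE)


def courtship_matrix(x_f: np.ndarray, x_m: np.ndarray, a: float) -> np.ndarray:
    """Courtship-effort proportions M[i, j] of male genotype j toward female i.

    ``M[i, j] = x_f[i] * x_m[j] * (1 + d*a) / y_j`` where the per-male
    normalizer ``y_j = sum_i x_f[i] * (1 + d*a)`` fixes each male genotype's
    total effort at its frequency: males differ in how they allocate
    courtship, not in how much they court.  Column sums equal ``x_m`` and the
    grand sum is 1.
    """
    x_f = np.asarray(x_f, dtype=float)
    x_m = np.asarray(x_m, dtype=float)
    pref = _preference_weight(a)
    y = pref.T @ x_f  # y_j
    return np.outer(x_f, x_m) * pref / y[None, :]


def pairing_matrix(M: np.ndarray, x_f: np.ndarray) -> np.ndarray:
    """Social-pairing proportions F[i, j] from the courtship matrix.

    Every female mates, so each female genotype's row of ``M`` is rescaled to
    sum to its frequency: ``F[i, j] = M[i, j] / z_i`` with
    ``z_i = sum_j M[i, j] / x_f[i]``.  A genotype absent from the female pool
    (``x_f[i] == 0``) contributes no matings; its row is all zeros.
    """
    x_f = np.asarray(x_f, dtype=float)
    row = M.sum(axis=1)
    scale = np.divide(x_f, row, out=np.zeros(4), where=row != 0.0)
    return M * scale[:, None]


def paternity_matrix(params: ModelParams) -> np.ndarray:
    """Within-pair paternity share Theta[i, j] of the social pair (i, j).

    Under the guarding trade-off a P2 male paired with a T1 female guards
    less, so ``Theta = theta - delta_theta`` there and ``theta`` elsewhere;
    under the care trade-off guarding is uniform and ``Theta = theta``
    everywhere.
    """
    k = np.outer(~T2_FEMALE, P2_MALE)
    if params.tradeoff is Tradeoff.GUARDING:
        return params.theta - params.delta_theta * k
    return np.full((4, 4), params.theta)


def epc_effort_matrix(params: ModelParams) -> np.ndarray:
    """EPC-seeking effort E[i, j] of male j socially paired with female i.

    ``e + delta_e`` for P2 males paired with T1 females, ``e`` otherwise
    (both trade-off variants).
    """
    k = np.outer(~T2_FEMALE, P2_MALE)
    return params.e + params.delta_e * k


def fecundity_matrix(params: ModelParams) -> np.ndarray:
    """Surviving offspring phi[i, j] per social pair (i, j).

    Care trade-off: ``1 + b`` for a fully caring pair, reduced to
    ``1 + b*(1 - delta)`` when a P2 male is paired with a T1 female.
    Guarding trade-off: all males care equally, normalized to 1.
    """
    if params.tradeoff is Tradeoff.GUARDING:
        return np.ones((4, 4))
    k = np.outer(~T2_FEMALE, P2_MALE)
    return 1.0 + params.b * (1.0 - params.delta * k)


def siring_shares(F: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Extra-pair siring shares rho[j]: male genotype j's share of all EPO.

    Extra-pair paternity is split in proportion to aggregate EPC effort,
    ``rho_j = sum_i F[i,j] E[i,j] / sum_ij F[i,j] E[i,j]``.
    """
    w = (F * E).sum(axis=0)
    return w / w.sum()


@dataclass(frozen=True)
class MatingTables:
    """All per-generation mating-stage tables (rows females i, columns males j)."""

    M: np.ndarray      #: courtship-effort proportions
    F: np.ndarray      #: social-pairing proportions
    Theta: np.ndarray  #: within-pair paternity shares
    E: np.ndarray      #: EPC-seeking efforts
    phi: np.ndarray    #: surviving offspring per pair
    rho: np.ndarray    #: extra-pair siring shares (4-vector)


def mating_tables(x: np.ndarray, params: ModelParams) -> MatingTables:
    """Compute every mating-stage table for zygote state ``x``."""
    x_f = viability_select_females(x, params.s_f)
    x_m = viability_select_males(x, params.s_m)
    M = courtship_matrix(x_f, x_m, params.a)
    F = pairing_matrix(M, x_f)
    E = epc_effort_matrix(params)
    return MatingTables(M=M, F=F, Theta=paternity_matrix(params), E=E,
                        phi=fecundity_matrix(params), rho=siring_shares(F, E))


@dataclass(frozen=True)
class OffspringTables:
    """Surviving-offspring proportions by (mother genotype, genetic father genotype)."""

    O_wp: np.ndarray  #: within-pair offspring (father = social mate)
    O_ep: np.ndarray  #: extra-pair offspring (father = extra-pair sire)


def offspring_tables(F: np.ndarray, Theta: np.ndarray, phi: np.ndarray,
                     rho: np.ndarray) -> OffspringTables:
    """Combine pairing, paternity, fecundity and siring shares into offspring.

    A pair (i, j) rears ``F_ij * phi_ij`` offspring, of which a share
    ``Theta_ij`` is within-pair; the remaining brood of mother i (summed over
    her possible social mates j') is extra-pair and its sires are drawn by
    ``rho``.  Extra-pair offspring thus inherit the survival context (phi,
    Theta) of the mother's social pair but the genotype of the sire.
    Entries are normalized by total surviving offspring ``N = sum F*phi``,
    so ``O_wp + O_ep`` sums to 1 exactly.
    """
    norm = (F * phi).sum()
    O_wp = F * Theta * phi / norm
    ep_brood = (F * phi * (1.0 - Theta)).sum(axis=1)  # per mother genotype
    O_ep = np.outer(ep_brood, rho) / norm
    return OffspringTables(O_wp=O_wp, O_ep=O_ep)


_TRANSMISSION_CACHE: dict[float, np.ndarray] = {}


def transmission_tensor(r: float) -> np.ndarray:
    """T[i, j, g] = P(haploid offspring genotype g | mother i, father j).

    The transient diploid passes each parental haplotype with probability
    ``(1 - r)/2`` and each recombinant haplotype with probability ``r/2``.
    """
    if not 0 <= r <= 0.5:
        raise ValueError(f"r must be in [0, 0.5], got {r}")
    key = float(r)
    if key not in _TRANSMISSION_CACHE:
        T = np.zeros((4, 4, 4))
        for i in range(4):
            pm, tm = divmod(i, 2)
            for j in range(4):
                pf, tf = divmod(j, 2)
                T[i, j, 2 * pm + tm] += (1 - r) / 2
                T[i, j, 2 * pf + tf] += (1 - r) / 2
                T[i, j, 2 * pm + tf] += r / 2
                T[i, j, 2 * pf + tm] += r / 2
        T.setflags(write=False)
        _TRANSMISSION_CACHE[key] = T
    return _TRANSMISSION_CACHE[key]


def transmit(O_total: np.ndarray, r: float) -> np.ndarray:
    """Zygote genotype frequencies from the total offspring table.

    ``O_total[i, j]`` is the proportion of surviving offspring with mother
    genotype i and genetic father genotype j; recombination at rate ``r``
    mixes the parental haplotypes.  The result is renormalized to guard
    against floating-point drift.
    """
    x = np.einsum("ij,ijg->g", np.asarray(O_total, dtype=float),
                  transmission_tensor(r))
    return x / x.sum()


def step(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """One full generation of the deterministic recursion.

    Viability selection (females then males) -> courtship -> pairing ->
    paternity / EPC-effort / fecundity tables -> extra-pair siring shares ->
    offspring accounting -> recombination and segregation.  Returns the
    next-generation zygote genotype frequencies.
    """
    x = np.asarray(x, dtype=float)
    tab = mating_tables(x, params)
    off = offspring_tables(tab.F, tab.Theta, tab.phi, tab.rho)
    return transmit(off.O_wp + off.O_ep, params.r)


# ---------------------------------------------------------------------------
# Equilibrium analysis
# ---------------------------------------------------------------------------

#: default L-infinity per-generation change below which iteration stops
CONVERGENCE_TOL = 1e-10
#: hard stop on per-generation change near neutral lines, where the primary
#: tolerance can only be approached slowly
STALL_TOL = 1e-13
MAX_GENERATIONS = 200_000
#: |eigenvalue modulus - 1| below this counts as a neutral direction
EIGEN_TOL = 1e-4
#: an allele counts as fixed / lost within this distance of 1 / 0
FIXATION_TOL = 1e-6


@dataclass
class Trajectory:
    """Recorded states of an iterated recursion run."""

    generations: int              #: generations actually iterated
    converged: bool
    recorded_at: np.ndarray       #: generation index of each stored state
    states: np.ndarray            #: stored states, shape (k, 4); first and last included
    final_summary: Summary

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def iterate_to_equilibrium(x0: np.ndarray, params: ModelParams,
                           tol: float = CONVERGENCE_TOL,
                           max_gen: int = MAX_GENERATIONS) -> Trajectory:
    """Iterate :func:`step` until the per-generation change falls below ``tol``.

    Stops when the L-infinity change of the state over one generation is
    below ``tol`` (converged), below :data:`STALL_TOL` (converged; reached
    only near neutral equilibrium lines), or after ``max_gen`` generations
    (flagged, not raised).  Stores the first, last and log-spaced
    intermediate states.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_gen < 1:
        raise ValueError("max_gen must be >= 1")
    x = validate_state(x0)
    recorded = [0]
    states = [x.copy()]
    next_snap = 1
    converged = False
    gen = 0
    for gen in range(1, max_gen + 1):
        x_new = step(x, params)
        np.clip(x_new, 0.0, None, out=x_new)
        x_new /= x_new.sum()
        delta = float(np.max(np.abs(x_new - x)))
        x = x_new
        if gen >= next_snap:
            recorded.append(gen)
            states.append(x.copy())
            next_snap = max(next_snap + 1, int(next_snap * 1.25))
        if delta < tol or delta < STALL_TOL:
            converged = True
            break
    if recorded[-1] != gen:
        recorded.append(gen)
        states.append(x.copy())
    if not converged:
        logger.warning("iterate_to_equilibrium: no convergence in %d generations", max_gen)
    return Trajectory(generations=gen, converged=converged,
                      recorded_at=np.array(recorded), states=np.array(states),
                      final_summary=summarize(x))


# -- analytic polymorphism conditions printed in the main text --------------


def condition_guarding(params: ModelParams) -> bool:
    """Polymorphic-line condition for the guarding trade-off.

    The relative EPC gain of a P2 male paired with a T1 female must exceed
    his relative paternity loss: ``delta_e/e > delta_theta/(1 - theta)``
    (strict).  With ``theta == 1`` there are no EPCs to gain from and the
    right side diverges, so the condition is False.
    """
    if params.theta >= 1.0:
        return False
    return params.delta_e / params.e > params.delta_theta / (1.0 - params.theta)


def condition_care(params: ModelParams) -> bool:
    """Preference-persistence condition for the care trade-off.

    Relative EPC gain must exceed the relative within-pair fecundity loss
    from reduced care: ``delta_e/e > b*delta*theta / ((1+b)*(1-theta))``.
    """
    if params.theta >= 1.0:
        return params.b * params.delta * params.theta == 0 and params.delta_e > 0
    rhs = params.b * params.delta * params.theta / ((1.0 + params.b) * (1.0 - params.theta))
    return params.delta_e / params.e > rhs


def condition_costly_trait(params: ModelParams) -> bool:
    """Whether a costly female trait can evolve: ``delta > s_f * (1 + 1/b)``.

    Requires the care reduction imposed on T1 females (relative fecundity
    change ``b*delta/(1+b)``) to exceed the trait's viability cost ``s_f``.
    With ``b == 0`` male care is worthless and a costly trait can never
    evolve (the threshold diverges).
    """
    if params.s_f == 0.0:
        return params.delta > 0.0
    if params.b == 0.0:
        return False
    return params.delta > params.s_f * (1.0 + 1.0 / params.b)


def condition_internal_costly(params: ModelParams) -> bool:
    """Stable-interior condition with a costly trait (care trade-off).

    ``s_f < 1 - theta`` and
    ``delta_e/e > b*delta*theta / ((1+b)*(1 - s_f - theta))``.
    """
    slack = 1.0 - params.s_f - params.theta
    if slack <= 0.0:
        return False
    rhs = params.b * params.delta * params.theta / ((1.0 + params.b) * slack)
    return params.delta_e / params.e > rhs


def condition_both_costly(params: ModelParams) -> bool:
    """Joint-cost bound for a polymorphism with costly trait and preference:
    ``(1 - s_f)*(1 - s_m) > theta``."""
    return (1.0 - params.s_f) * (1.0 - params.s_m) > params.theta


def condition_flags(params: ModelParams) -> dict[str, bool]:
    """All analytic condition booleans for ``params`` in one mapping."""
    return {
        "guarding": condition_guarding(params),
        "care": condition_care(params),
        "costly_trait": condition_costly_trait(params),
        "internal_costly": condition_internal_costly(params),
        "both_costly": condition_both_costly(params),
    }


def edge_equilibrium_p2(params: ModelParams) -> float | None:
    """Closed-form polymorphic equilibrium of P2 on the trait-lost edge t2 = 0.

    Care trade-off only.  Without a preference cost::

        p2* = (delta_e*(1+b)*(1-theta) - b*e*delta*theta) / (delta_e*b*delta)

    and with a male viability cost ``s_m`` the analogous expression below.
    Returns ``p2*`` when it lies strictly inside (0, 1); otherwise ``None``
    (no polymorphic edge equilibrium).  The returned value is a fixed point
    of the t2 = 0 edge dynamics of :func:`step`.
    """
    if params.tradeoff is not Tradeoff.CARE:
        raise ValueError("edge_equilibrium_p2 is defined for the care trade-off only")
    e, de, b, th, d, sm = (params.e, params.delta_e, params.b, params.theta,
                           params.delta, params.s_m)
    if sm == 0.0:
        den = de * b * d
        if den == 0.0:
            return None
        p = (de * (1.0 + b) * (1.0 - th) - b * e * d * th) / den
    else:
        den = (de * (1.0 - sm) - e * sm) * (sm * (1.0 + b * (1.0 - d)) + b * d)
        if den == 0.0:
            return None
        num = (de * (1.0 + b) * (1.0 - sm) * (1.0 - th)
               - e * (b * d * th + sm * (1.0 + b - b * d * th)))
        p = num / den
    return float(p) if 0.0 < p < 1.0 else None


# -- numerical stability classification -------------------------------------


class Stability(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    NEUTRAL_LINE = "neutral_line"


@dataclass
class EquilibriumReport:
    """A fixed point with its local linearization and analytic context."""

    state: np.ndarray
    summary: Summary
    eigenvalues: np.ndarray        #: moduli of the 3x3 one-step Jacobian spectrum
    stability: Stability
    condition_flags: dict[str, bool]


def _coords_to_state(p2: float, t2: float, D: float) -> np.ndarray:
    # polynomial inverse of summarize(); intentionally no simplex clipping so
    # that finite differences remain smooth across boundaries
    x4 = D + p2 * t2
    x3 = p2 - x4
    x2 = t2 - x4
    return np.array([1.0 - x2 - x3 - x4, x2, x3, x4])


def _step_in_coords(c: np.ndarray, params: ModelParams) -> np.ndarray:
    s = summarize(step(_coords_to_state(*c), params))
    return np.array(s)


def classify_stability(x_star: np.ndarray, params: ModelParams,
                       eps: float = 1e-6,
                       eigen_tol: float = EIGEN_TOL,
                       residual_tol: float = 1e-8) -> EquilibriumReport:
    """Classify a fixed point by the spectrum of the one-step Jacobian.

    The Jacobian of the generation map is built in (p2, t2, D) coordinates
    by central finite differences with step ``eps`` (the coordinate change
    is a polynomial bijection of the simplex, so its spectrum equals that of
    the map restricted to the simplex).  Classes: ``STABLE`` if every
    eigenvalue modulus is below ``1 - eigen_tol``; ``NEUTRAL_LINE`` if
    exactly one modulus lies within ``eigen_tol`` of 1 and the rest are
    below (the signature of a line of neutrally stable equilibria);
    ``UNSTABLE`` otherwise.
    """
    x_star = np.asarray(x_star, dtype=float)
    residual = float(np.max(np.abs(step(x_star, params) - x_star)))
    if residual > residual_tol:
        raise ValueError(f"not a fixed point: one-step residual {residual:.3e} "
                         f"exceeds {residual_tol:.1e}")
    c0 = np.array(summarize(x_star))
    J = np.empty((3, 3))
    for k in range(3):
        hi = c0.copy()
        lo = c0.copy()
        hi[k] += eps
        lo[k] -= eps
        J[:, k] = (_step_in_coords(hi, params) - _step_in_coords(lo, params)) / (2 * eps)
    moduli = np.sort(np.abs(np.linalg.eigvals(J)))[::-1]
    near_one = np.abs(moduli - 1.0) <= eigen_tol
    below = moduli < 1.0 - eigen_tol
    if below.all():
        stability = Stability.STABLE
    elif near_one.sum() == 1 and below.sum() == 2:
        stability = Stability.NEUTRAL_LINE
    else:
        stability = Stability.UNSTABLE
    return EquilibriumReport(state=x_star, summary=summarize(x_star),
                             eigenvalues=moduli, stability=stability,
                             condition_flags=condition_flags(params))


def _classify_outcome(s: Summary, tol: float = FIXATION_TOL) -> str:
    if s.t2 >= 1.0 - tol:
        return "t2_fixed"
    if s.p2 <= tol:
        return "p2_lost"
    if tol < s.p2 < 1.0 - tol and tol < s.t2 < 1.0 - tol:
        return "interior"
    return "other"


def basin_sweep(params: ModelParams,
                initial_grid: Iterable[tuple[float, float]],
                tol: float = CONVERGENCE_TOL,
                max_gen: int = MAX_GENERATIONS) -> pd.DataFrame:
    """Iterate to equilibrium from each initial (p2, t2) point (D = 0).

    Returns one row per start with the final summary and an outcome class:
    ``t2_fixed`` (trait allele fixed), ``p2_lost`` (preference allele lost),
    ``interior`` (both loci polymorphic), or ``other``.
    """
    rows = []
    for p2_0, t2_0 in initial_grid:
        traj = iterate_to_equilibrium(state_from_freqs(p2_0, t2_0, 0.0),
                                      params, tol=tol, max_gen=max_gen)
        s = traj.final_summary
        rows.append({"p2_0": p2_0, "t2_0": t2_0,
                     "p2": s.p2, "t2": s.t2, "D": s.D,
                     "outcome": _classify_outcome(s),
                     "converged": traj.converged,
                     "generations": traj.generations})
    return pd.DataFrame(rows)


#: default starts used when probing equilibria numerically in region maps
_PROBE_STARTS = ((0.1, 0.1), (0.5, 0.5), (0.9, 0.9), (0.9, 0.2), (0.2, 0.9))


def _analytic_class(p: ModelParams) -> str:
    """Qualitative region label from the printed closed-form conditions."""
    if p.tradeoff is Tradeoff.GUARDING:
        if p.s_f > 0:
            return "trait_lost"
        return "neutral_line" if condition_guarding(p) else "preference_lost"
    labels = []
    if condition_costly_trait(p):
        labels.append("trait_line")
    if condition_internal_costly(p) and (p.s_m == 0 or condition_both_costly(p)):
        labels.append("interior")
    return "+".join(labels) if labels else "trait_cannot_evolve"


def region_map(params_base: ModelParams,
               axis1: tuple[str, tuple[float, float], int],
               axis2: tuple[str, tuple[float, float], int],
               numeric: bool = False,
               max_gen: int = 20_000) -> pd.DataFrame:
    """Classify each cell of a 2-D parameter grid.

    ``axis1``/``axis2`` are ``(param_name, (lo, hi), n)``.  Each cell gets
    the analytic condition flags and a qualitative analytic class; with
    ``numeric=True`` the boundary equilibria (0,0,0) and (1,0,0) and the
    closed-form edge point (care trade-off) are additionally classified by
    Jacobian eigenvalues, and short iterations from a standard set of starts
    record which outcome classes are actually reached.
    """
    name1, (lo1, hi1), n1 = axis1
    name2, (lo2, hi2), n2 = axis2
    rows = []
    for v1 in np.linspace(lo1, hi1, n1):
        for v2 in np.linspace(lo2, hi2, n2):
            try:
                p = replace(params_base, **{name1: float(v1), name2: float(v2)})
            except ValueError:
                continue  # grid point outside the parameter domain
            row = {name1: v1, name2: v2, **condition_flags(p),
                   "analytic_class": _analytic_class(p)}
            if numeric:
                row.update(_numeric_cell(p, max_gen))
            rows.append(row)
    return pd.DataFrame(rows)


def _numeric_cell(p: ModelParams, max_gen: int) -> dict:
    out: dict = {}
    for label, (p2c, t2c) in (("origin", (0.0, 0.0)), ("p2_corner", (1.0, 0.0))):
        try:
            rep = classify_stability(state_from_freqs(p2c, t2c), p)
            out[f"{label}_stable"] = rep.stability is Stability.STABLE
        except ValueError:
            out[f"{label}_stable"] = False
    edge = edge_equilibrium_p2(p) if p.tradeoff is Tradeoff.CARE else None
    out["edge_p2"] = np.nan if edge is None else edge
    reached = {
        _classify_outcome(
            iterate_to_equilibrium(state_from_freqs(*s), p, tol=1e-9,
                                   max_gen=max_gen).final_summary)
        for s in _PROBE_STARTS
    }
    out["reached"] = "+".join(sorted(reached))
    return out


# ---------------------------------------------------------------------------
# Individual-based Monte-Carlo oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ABMConfig:
    """Configuration of the finite-population stochastic simulation."""

    N: int                 #: individuals per sex
    replicates: int
    generations: int
    seed: int
    params: ModelParams

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


def _abm_offspring_dist(fem: np.ndarray, mal: np.ndarray, params: ModelParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Offspring genotype distribution for one finite-population generation.

    ``fem``/``mal`` are genotype counts of the N-female and N-male pools.
    Viability survival, per-female social-mate choice and the implied
    within-/extra-pair offspring distribution all use the realized
    finite-population tables, so the expectation of the returned
    distribution is exactly the deterministic recursion applied to the
    realized frequencies.
    """
    N = fem.sum()
    x_f = viability_select_females(fem / N, params.s_f)
    x_m = viability_select_males(mal / N, params.s_m)
    fem_pool = rng.multinomial(N, x_f)
    mal_pool = rng.multinomial(N, x_m)
    xf = fem_pool / N
    xm = mal_pool / N
    # each female chooses a social mate in proportion to courtship effort
    # directed at her genotype (realized male pool)
    M = courtship_matrix(xf, xm, params.a)
    pair_counts = np.zeros((4, 4))
    for i in range(4):
        if fem_pool[i] == 0:
            continue
        row = M[i]
        tot = row.sum()
        if tot == 0.0:  # degenerate male pool; mate uniformly among present males
            row = xm
            tot = row.sum()
        pair_counts[i] = rng.multinomial(fem_pool[i], row / tot)
    F_hat = pair_counts / N
    E = epc_effort_matrix(params)
    off = offspring_tables(F_hat, paternity_matrix(params),
                           fecundity_matrix(params), siring_shares(F_hat, E))
    dist = transmit(off.O_wp + off.O_ep, params.r)
    np.clip(dist, 0.0, None, out=dist)
    return dist / dist.sum()


def abm_one_generation(x0: np.ndarray, params: ModelParams, N: int,
                       replicates: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-mean and standard error of (p2, t2, D) after one ABM generation.

    Parent pools are resampled from ``x0`` each replicate, so this measures
    the expected one-generation change at fixed parent frequencies — the
    quantity the deterministic :func:`step` predicts.
    """
    x0 = validate_state(x0)
    out = np.empty((replicates, 3))
    for rep in range(replicates):
        rng = np.random.default_rng(seed + rep)
        fem = rng.multinomial(N, x0)
        mal = rng.multinomial(N, x0)
        dist = _abm_offspring_dist(fem, mal, params, rng)
        kids = rng.multinomial(2 * N, dist)
        out[rep] = np.array(summarize(kids / (2 * N)))
    return out.mean(axis=0), out.std(axis=0, ddof=1) / math.sqrt(replicates)


def simulate_abm(config: ABMConfig, x0: np.ndarray) -> pd.DataFrame:
    """Run the individual-based simulation and average over replicates.

    Each replicate holds N females and N males.  Per generation: viability
    survival (multinomial resampling from the post-selection distribution),
    per-female social-mate choice weighted by courtship effort, then
    multinomial offspring production over the (mother, genetic father)
    outcome distribution implied by the realized mating tables — which makes
    the ABM's expectation exactly the deterministic recursion, the point of
    the oracle.  Identical ``seed`` and config give bit-identical output;
    replicate ``k`` uses stream ``seed + k``.

    Returns a frame with columns ``generation, mean_p2, se_p2, mean_t2,
    se_t2, mean_D, se_D`` (zygote summaries, generation 0 = initial sample).
    """
    x0 = validate_state(x0)
    p = config.params
    n_gen = config.generations
    stats = np.empty((config.replicates, n_gen + 1, 3))
    for rep in range(config.replicates):
        rng = np.random.default_rng(config.seed + rep)
        fem = rng.multinomial(config.N, x0)
        mal = rng.multinomial(config.N, x0)
        for gen in range(n_gen + 1):
            stats[rep, gen] = np.array(summarize((fem + mal) / (2 * config.N)))
            if gen == n_gen:
                break
            dist = _abm_offspring_dist(fem, mal, p, rng)
            fem = rng.multinomial(config.N, dist)
            mal = rng.multinomial(config.N, dist)
    mean = stats.mean(axis=0)
    if config.replicates > 1:
        se = stats.std(axis=0, ddof=1) / math.sqrt(config.replicates)
    else:
        se = np.zeros_like(mean)
    return pd.DataFrame({
        "generation": np.arange(n_gen + 1),
        "mean_p2": mean[:, 0], "se_p2": se[:, 0],
        "mean_t2": mean[:, 1], "se_t2": se[:, 1],
        "mean_D": mean[:, 2], "se_D": se[:, 2],
    })


# ---------------------------------------------------------------------------
# Configuration and export plumbing
# ---------------------------------------------------------------------------

_PARAM_NAMES = {f.name for f in fields(ModelParams)}


def params_from_mapping(mapping: Mapping[str, object]) -> ModelParams:
    """Build :class:`ModelParams` from a flat mapping; unknown keys rejected."""
    unknown = set(mapping) - _PARAM_NAMES
    if unknown:
        raise ValueError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
    kwargs: dict = {}
    for k, v in mapping.items():
        kwargs[k] = str(v) if k == "tradeoff" else float(v)  # type: ignore[arg-type]
    return ModelParams(**kwargs)


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; keys must be ModelParams
    field names or command options handled by the caller.
    """
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


def trajectory_to_dataframe(traj: Trajectory) -> pd.DataFrame:
    """Recorded trajectory states as a frame: generation, x1..x4, p2, t2, D."""
    df = pd.DataFrame(traj.states, columns=["x1", "x2", "x3", "x4"])
    df.insert(0, "generation", traj.recorded_at)
    summ = np.array([summarize(s) for s in traj.states])
    df["p2"], df["t2"], df["D"] = summ[:, 0], summ[:, 1], summ[:, 2]
    return df


def write_csv_with_params(df: pd.DataFrame, path: str | Path,
                          params: ModelParams, extra: Mapping[str, object] | None = None) -> None:
    """Write a CSV whose header comments embed the resolved parameter set."""
    meta = {**params.to_dict(), **(extra or {})}
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Figure-data regeneration protocols
# ---------------------------------------------------------------------------

#: captioned parameter sets behind each published panel
FIGURE_PARAMS = {
    "fig1": ModelParams(a=1.0, e=0.8, delta_e=0.7, theta=0.8, delta_theta=0.1,
                        tradeoff=Tradeoff.GUARDING),
    "fig2a": ModelParams(a=1.5, e=0.8, delta_e=0.1, theta=0.8, delta=0.1, b=0.8,
                         tradeoff=Tradeoff.CARE),
    "fig2b": ModelParams(a=1.5, e=0.8, delta_e=0.8, theta=0.8, delta=0.1, b=0.8,
                         tradeoff=Tradeoff.CARE),
    "fig3a": ModelParams(a=2.0, e=0.8, b=0.8, theta=0.7, s_f=0.05,
                         delta=0.1, delta_e=0.1, tradeoff=Tradeoff.CARE),
    "fig3b": ModelParams(a=2.0, e=0.8, b=0.8, theta=0.85, s_f=0.2,
                         delta=0.1, delta_e=0.1, tradeoff=Tradeoff.CARE),
}

#: (s_f, s_m, theta) of the four costly-preference panels
_FIG4_PANELS = {"a": (0.05, 0.05, 0.7), "b": (0.05, 0.25, 0.8),
                "c": (0.17, 0.05, 0.85), "d": (0.15, 0.15, 0.9)}

GRID_3X3 = tuple((p, t) for p in (0.1, 0.5, 0.9) for t in (0.1, 0.5, 0.9))


def figures_protocol(name: str, outdir: str | Path, grid_n: int = 41,
                     numeric: bool = False) -> list[Path]:
    """Regenerate the numerical content behind a published figure as CSV files.

    ``fig1``: equilibrium (p2, t2) curves under the guarding trade-off, for
    three values of ``delta_e`` (panel a) and of ``a`` (panel b), traced by
    iterating to the neutral equilibrium line from a ladder of initial
    states.  ``fig2``: the nine-trajectory basin sweeps of both care-model
    panels.  ``fig3``/``fig4``: (delta, delta_e) region classifications for
    the captioned cost/paternity parameter sets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, fname: str, params: ModelParams, **extra) -> None:
        path = outdir / fname
        write_csv_with_params(df, path, params, extra)
        written.append(path)

    if name == "fig1":
        base = FIGURE_PARAMS["fig1"]
        starts = [(0.5, t) for t in np.linspace(0.05, 0.95, 10)]
        for label, pname, values in (("a", "delta_e", (0.5, 0.6, 0.7)),
                                     ("b", "a", (0.5, 1.0, 2.0))):
            frames = []
            for v in values:
                p = replace(base, **{pname: v})
                df = basin_sweep(p, starts)
                df.insert(0, pname, v)
                frames.append(df)
            emit(pd.concat(frames, ignore_index=True),
                 f"fig1{label}_equilibria.csv", base, varied=pname)
    elif name == "fig2":
        for panel in ("a", "b"):
            p = FIGURE_PARAMS[f"fig2{panel}"]
            frames = []
            for p2_0, t2_0 in GRID_3X3:
                traj = iterate_to_equilibrium(state_from_freqs(p2_0, t2_0), p)
                df = trajectory_to_dataframe(traj)
                df.insert(0, "t2_0", t2_0)
                df.insert(0, "p2_0", p2_0)
                frames.append(df)
            emit(pd.concat(frames, ignore_index=True),
                 f"fig2{panel}_trajectories.csv", p)
    elif name == "fig3":
        for panel in ("a", "b"):
            p = FIGURE_PARAMS[f"fig3{panel}"]
            df = region_map(p, ("delta", (0.0, 0.6), grid_n),
                            ("delta_e", (0.0, 1.2), grid_n), numeric=numeric)
            emit(df, f"fig3{panel}_regions.csv", p)
    elif name == "fig4":
        for panel, (s_f, s_m, theta) in _FIG4_PANELS.items():
            p = ModelParams(a=2.0, e=0.8, b=0.8, theta=theta, s_f=s_f, s_m=s_m,
                            delta=0.1, delta_e=0.1, tradeoff=Tradeoff.CARE)
            df = region_map(p, ("delta", (0.0, 0.6), grid_n),
                            ("delta_e", (0.0, 1.2), grid_n), numeric=numeric)
            emit(df, f"fig4{panel}_regions.csv", p)
    else:
        raise ValueError(f"unknown figure {name!r}; expected fig1..fig4")
    return written
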