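"""Single-site genotype imputation through a pedigree.

Untyped individuals are imputed from typed relatives by *forced* haplotype
transmission: an allele is assigned to a haplotype only when Mendelian logic
leaves no alternative (a homozygous parent fixes the transmitted allele; a
typed heterozygous child with one resolved haplotype fixes the other; a
child's resolved transmitted allele proves its untyped parent carries that
allele).  No probabilistic peeling is performed, which keeps every assignment
checkable against exhaustive enumeration.  Haplotypes left unresolved
contribute their conditional expectation — the mean of the transmitting
parent's haplotype values when a parent is in the pedigree, the population
allele frequency ``p`` otherwise — so the resulting dosages
``theta_hat = E(theta | typed data)`` are calibrated (population mean 2p).

The informativeness of the imputation is scored by the variance-ratio metric

    info = Var(per-haplotype imputed expectations) / p(1 - p),

which is 0 when the same value is always imputed, 1 when imputation is fully
informative, and asymptotically equals the squared correlation between the
imputed and true allele counts.

This is deliberately a single-site, genealogy-only simplification of
population-scale long-range-haplotype imputation: no genotyping-array
haplotypes, no recombination, autosomal sites only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import Pedigree

logger = logging.getLogger("cgdseek")


class MendelianInconsistencyError(ValueError):
    """Typed genotypes at the site cannot be produced by any transmission."""


class UndefinedInformationError(ValueError):
    """Information score undefined for monomorphic allele frequency."""


@dataclass
class HaplotypeAssignment:
    """Resolved parental-origin alleles of one individual (None = unknown)."""

    individual_id: str
    paternal_allele: int | None = None
    maternal_allele: int | None = None


@dataclass
class DosageVector:
    """Imputed expected minor-allele counts for a pedigree at one site."""

    ids: list[str]
    theta_hat: np.ndarray  # per-individual expected allele count in [0, 2]
    hap_expectations: np.ndarray  # (n, 2) per-haplotype expectations in [0, 1]
    p: float  # allele frequency used for unresolved haplotypes
    typed_mask: np.ndarray  # boolean: directly genotyped

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ids, self.theta_hat.tolist()))


# ---------------------------------------------------------------------------
# Internal haplotype state
# ---------------------------------------------------------------------------


class _Haps:
    """Per-individual haplotype knowledge at a single biallelic site.

    ``pat``/``mat`` hold alleles whose parental origin is proven.
    ``floating`` holds an allele proven present on one of the (still
    origin-unlabelled) haplotypes, e.g. deduced from a transmitted allele
    observed in a child.  ``het`` marks an individual proven heterozygous
    (typed count 1, or both alleles proven present) whose origins may still
    be unknown.
    """

    __slots__ = ("pat", "mat", "floating", "het", "count")

    def __init__(self, count: int | None):
        self.count = count
        self.pat: int | None = None
        self.mat: int | None = None
        self.floating: int | None = None
        self.het = False
        if count == 0:
            self.pat, self.mat = 0, 0
        elif count == 2:
            self.pat, self.mat = 1, 1
        elif count == 1:
            self.het = True

    def known_values(self) -> set[int]:
        vals = {v for v in (self.pat, self.mat, self.floating) if v is not None}
        if self.het:
            vals |= {0, 1}
        return vals

    def resolved_hom(self) -> int | None:
        """The allele surely transmitted to every child, if forced."""
        if self.count in (0, 2):
            return self.count // 2
        if self.pat is not None and self.pat == self.mat:
            return self.pat
        return None

    def carries(self, allele: int) -> bool:
        """Is the individual proven to carry `allele` on some haplotype?"""
        return allele in self.known_values()

    def can_carry(self, allele: int) -> bool:
        """Could the individual carry `allele` given current knowledge?"""
        if self.count == 0:
            return allele == 0
        if self.count == 2:
            return allele == 1
        if self.het:
            return True
        if self.pat is not None and self.mat is not None:
            return allele in (self.pat, self.mat)
        return True


def _propagate(pedigree: Pedigree, counts: Mapping[str, int | None]) -> dict[str, _Haps]:
    """Fixed-point propagation of forced haplotype assignments."""
    state = {ind.id: _Haps(counts.get(ind.id)) for ind in pedigree}

    def set_side(h: _Haps, side: str, value: int, who: str) -> bool:
        cur = getattr(h, side)
        if cur is not None:
            if cur != value:
                raise MendelianInconsistencyError(
                    f"conflicting forced alleles for {who} ({side}): {cur} vs {value}"
                )
            return False
        setattr(h, side, value)
        # a proven heterozygote with one side resolved has the other forced
        other = "mat" if side == "pat" else "pat"
        if h.het and getattr(h, other) is None:
            setattr(h, other, 1 - value)
        if h.count is not None and h.pat is not None and h.mat is not None:
            if h.pat + h.mat != h.count:
                raise MendelianInconsistencyError(
                    f"haplotypes ({h.pat},{h.mat}) contradict genotype {h.count} of {who}"
                )
        return True

    def add_known_allele(h: _Haps, value: int, who: str) -> bool:
        """Record that `who` surely carries `value` on some haplotype."""
        if h.carries(value):
            return False
        if not h.can_carry(value):
            raise MendelianInconsistencyError(
                f"{who} proven to carry allele {value} it cannot carry"
            )
        # one origin side fixed to the complement: `value` sits on the other
        if h.pat is not None and h.mat is None:
            return set_side(h, "mat", value, who)
        if h.mat is not None and h.pat is None:
            return set_side(h, "pat", value, who)
        if h.floating is None:
            h.floating = value
            return True
        # floating holds the complement (carries() returned False), so both
        # alleles are proven present: the individual is heterozygous
        h.floating = None
        h.het = True
        return True

    def resolve_floating(h: _Haps, who: str) -> bool:
        """Absorb a floating allele once an origin side becomes known."""
        if h.floating is None:
            return False
        if h.pat is not None and h.mat is not None:
            if h.floating not in (h.pat, h.mat):
                raise MendelianInconsistencyError(
                    f"{who} carries allele {h.floating} on neither resolved haplotype"
                )
            h.floating = None
            return True
        for known, free in (("pat", "mat"), ("mat", "pat")):
            kv = getattr(h, known)
            if kv is not None and getattr(h, free) is None and h.floating != kv:
                val = h.floating
                h.floating = None
                set_side(h, free, val, who)
                return True
        return False

    changed = True
    guard = 0
    while changed:
        changed = False
        guard += 1
        if guard > 10 * len(state) + 100:  # pragma: no cover - safety valve
            raise RuntimeError("haplotype propagation failed to converge")
        for ind in pedigree:
            h = state[ind.id]
            for side, pid in (("pat", ind.father_id), ("mat", ind.mother_id)):
                if pid is None or pid not in pedigree.individuals:
                    continue
                hp = state[pid]
                # downward: a homozygous parent forces the transmitted allele
                forced = hp.resolved_hom()
                if forced is not None:
                    if getattr(h, side) is None:
                        if not h.can_carry(forced):
                            raise MendelianInconsistencyError(
                                f"child {ind.id} cannot receive allele {forced} "
                                f"forced by parent {pid}"
                            )
                        changed |= set_side(h, side, forced, ind.id)
                    elif getattr(h, side) != forced:
                        raise MendelianInconsistencyError(
                            f"child {ind.id} {side} allele {getattr(h, side)} "
                            f"contradicts parent {pid} homozygous for {forced}"
                        )
                # upward: a resolved transmitted allele proves the parent carries it
                val = getattr(h, side)
                if val is not None:
                    changed |= add_known_allele(hp, val, pid)
            changed |= resolve_floating(h, ind.id)
    return state


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def phase_by_transmission(
    pedigree: Pedigree, counts: Mapping[str, int | None]
) -> dict[str, HaplotypeAssignment]:
    """Assign parental origin of alleles wherever transmission forces it.

    ``counts`` maps individual id -> alternate-allele count (None = untyped).
    Raises :class:`MendelianInconsistencyError` on impossible configurations
    (e.g. a homozygous-reference child of a homozygous-alternate parent), so
    callers can exclude and log the site.
    """
    state = _propagate(pedigree, counts)
    return {
        iid: HaplotypeAssignment(iid, paternal_allele=h.pat, maternal_allele=h.mat)
        for iid, h in state.items()
    }


def impute_untyped(
    pedigree: Pedigree,
    counts: Mapping[str, int | None],
    p: float,
) -> DosageVector:
    """Expected minor-allele counts for every pedigree member.

    Typed individuals keep their observed counts.  For untyped individuals,
    haplotypes forced by transmission chains are assigned their proven
    allele; each unresolved haplotype contributes the mean of its
    transmitting parent's haplotype expectations (computed founders-first),
    or the population frequency ``p`` when no parent is in the pedigree.
    """
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"allele frequency must lie in [0, 1], got {p}")
    state = _propagate(pedigree, counts)

    exps: dict[str, tuple[float, float]] = {}
    for iid in pedigree.topological_order():
        ind = pedigree[iid]
        h = state[iid]

        def transmit_exp(pid: str | None) -> float:
            if pid is None or pid not in pedigree.individuals:
                return p
            a, b = exps[pid]
            return (a + b) / 2.0

        if h.pat is not None and h.mat is not None:
            e = (float(h.pat), float(h.mat))
        elif h.het:
            # proven heterozygote with unresolved origins: multiset {0, 1}
            e = (0.0, 1.0)
        else:
            e_pat = float(h.pat) if h.pat is not None else transmit_exp(ind.father_id)
            e_mat = float(h.mat) if h.mat is not None else transmit_exp(ind.mother_id)
            if h.floating is not None:
                # an allele proven present without an origin label occupies
                # one haplotype; the other keeps the averaged expectation
                e = (float(h.floating), (e_pat + e_mat) / 2.0)
            else:
                e = (e_pat, e_mat)
        exps[iid] = e

    ids = [ind.id for ind in pedigree]
    hap = np.array([exps[i] for i in ids], dtype=float)
    typed = np.array([counts.get(i) is not None for i in ids])
    theta = hap.sum(axis=1)
    observed = np.array([c if (c := counts.get(i)) is not None else -1 for i in ids])
    assert np.all(theta[typed] == observed[typed]), "typed dosages must equal observed"
    return DosageVector(ids=ids, theta_hat=theta, hap_expectations=hap, p=p, typed_mask=typed)


def imputation_information(dosages: DosageVector) -> float:
    """Variance-ratio informativeness of an imputation.

    ``Var`` of the per-haplotype imputed expectations divided by ``p(1-p)``;
    0 when the same value is always imputed, 1 when fully informative,
    asymptotically the squared correlation with the true allele counts.
    Values may marginally exceed 1 through sampling noise; clip only for
    reporting.
    """
    p = dosages.p
    if p <= 0.0 or p >= 1.0:
        raise UndefinedInformationError(f"information undefined for p = {p}")
    if len(dosages.ids) < 2:
        raise ValueError("need at least 2 individuals")
    haps = dosages.hap_expectations.ravel()
    return float(np.var(haps) / (p * (1.0 - p)))
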