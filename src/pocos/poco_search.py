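"""Greedy discovery of disjoint population-covering locus sets (PoCos).

A PoCo is a set of loci whose selected binary genotype profiles jointly
cover every case sample while covering as few control samples as possible.
Sets are grown greedily: at each step the candidate locus maximizing the
coverage gain

    delta(c) = |new cases covered| / |S1| - |new controls covered| / |S0|

is added, where "new" means not yet covered by the growing set. Only
candidates covering at least one uncovered case are eligible (this
guarantees progress). Ties are broken by the larger count of newly covered
cases, then the larger |D| of the locus's selected genotype model, then the
lexicographically smallest locus id — a deterministic, input-order-
independent rule. Complete sets are recorded and their loci removed from
the candidate pool; discovery stops at the first incomplete attempt, whose
loci are discarded by default.

The algorithm is a heuristic: it does not guarantee the minimum possible
control coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Callable, Iterable, Sequence

import numpy as np

from .genotype_models import BinaryProfileSet
from .gwas_io import GwasDataset


@dataclass
class CoverageState:
    """Covered case/control sets of a growing locus set."""

    loci: list[str]
    covered_cases: set[int]
    covered_controls: set[int]

    @property
    def covered(self) -> set[int]:
        return self.covered_cases | self.covered_controls


@dataclass
class PoCo:
    """One discovered locus set with its coverage bookkeeping."""

    loci: list[str]
    n_cases_covered: int
    n_controls_covered: int
    trace: list[tuple[str, float]]  # (locus added, delta at addition)
    complete: bool = True

    def __len__(self) -> int:
        return len(self.loci)

    def as_dict(self) -> dict:
        return {
            "loci": list(self.loci),
            "n_cases_covered": self.n_cases_covered,
            "n_controls_covered": self.n_controls_covered,
            "trace": [[lid, float(d)] for lid, d in self.trace],
            "complete": self.complete,
        }


@dataclass
class PoCoCollection:
    """Ordered collection of pairwise locus-disjoint PoCos."""

    pocos: list[PoCo] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pocos)

    def __iter__(self):
        return iter(self.pocos)

    def __getitem__(self, i) -> PoCo:
        return self.pocos[i]

    def all_loci(self) -> set[str]:
        out: set[str] = set()
        for p in self.pocos:
            out.update(p.loci)
        return out


def delta(
    candidate_idx: int,
    covered: np.ndarray,
    M: np.ndarray,
    phenotype: np.ndarray,
) -> float:
    """Coverage gain of one candidate given the currently covered samples.

    With nothing covered this reduces to the locus's selected-model D score.
    """
    phenotype = np.asarray(phenotype)
    n1 = int((phenotype == 1).sum())
    n0 = int((phenotype == 0).sum())
    unc = ~np.asarray(covered, dtype=bool)
    row = M[candidate_idx]
    new_cases = int((row & unc & (phenotype == 1)).sum())
    new_ctrls = int((row & unc & (phenotype == 0)).sum())
    return new_cases / n1 - new_ctrls / n0


class _GreedyEngine:
    """Vectorized greedy cover over a fixed binary matrix."""

    def __init__(
        self,
        M: np.ndarray,
        phenotype: np.ndarray,
        locus_ids: Sequence[str],
        tie_magnitude: np.ndarray | None = None,
        reach: "np.ndarray | None" = None,
    ):
        self.M = np.asarray(M, dtype=bool)
        self._Mf = self.M.astype(np.float32)  # BLAS matvec is the hot path
        self.phenotype = np.asarray(phenotype)
        self.case = self.phenotype == 1
        self.n1 = int(self.case.sum())
        self.n0 = int((~self.case).sum())
        self.ids = list(locus_ids)
        self.tie_mag = (
            np.zeros(len(self.ids)) if tie_magnitude is None else np.asarray(tie_magnitude)
        )
        # lexicographic rank of locus ids for the final tie-break
        order = sorted(range(len(self.ids)), key=lambda i: self.ids[i])
        self.id_rank = np.empty(len(self.ids), dtype=np.int64)
        self.id_rank[order] = np.arange(len(self.ids))
        self.reach = reach  # (n_loci, n_loci) bool: within hop bound

    def grow(
        self, pool: np.ndarray, target_cases: int
    ) -> tuple[PoCo, np.ndarray]:
        """Grow one set from ``pool``; returns the (possibly incomplete) PoCo."""
        covered = np.zeros(self.M.shape[1], dtype=bool)
        members: list[int] = []
        trace: list[tuple[str, float]] = []
        frontier = np.zeros(len(self.ids), dtype=bool)
        n_cases_cov = 0

        while n_cases_cov < target_cases:
            unc = ~covered
            newc = np.rint(
                self._Mf @ (self.case & unc).astype(np.float32)
            ).astype(np.int64)
            eligible = pool & (newc > 0)
            if members and self.reach is not None:
                eligible &= frontier
            if not eligible.any():
                break
            newt = np.rint(
                self._Mf @ (~self.case & unc).astype(np.float32)
            ).astype(np.int64)
            d = newc / self.n1 - newt / self.n0

            cand = np.flatnonzero(eligible)
            d_c = d[cand]
            best = cand[d_c >= d_c.max() - 1e-15]
            if len(best) > 1:
                nb = newc[best]
                best = best[nb == nb.max()]
            if len(best) > 1:
                mb = self.tie_mag[best]
                best = best[mb >= mb.max() - 1e-15]
            if len(best) > 1:
                best = best[[np.argmin(self.id_rank[best])]]
            chosen = int(best[0])

            members.append(chosen)
            trace.append((self.ids[chosen], float(d[chosen])))
            covered |= self.M[chosen]
            pool = pool.copy()
            pool[chosen] = False
            if self.reach is not None:
                frontier |= self.reach[chosen]
            n_cases_cov = int((covered & self.case).sum())

        poco = PoCo(
            loci=[self.ids[i] for i in members],
            n_cases_covered=n_cases_cov,
            n_controls_covered=int((covered & ~self.case).sum()),
            trace=trace,
            complete=n_cases_cov >= target_cases,
        )
        return poco, np.array(members, dtype=np.int64)

    def discover(
        self,
        pool: np.ndarray,
        coverage_fraction: float = 1.0,
        emit_partial: bool = False,
    ) -> PoCoCollection:
        target = ceil(coverage_fraction * self.n1)
        pool = pool.copy()
        collection = PoCoCollection()
        while pool.any():
            poco, members = self.grow(pool, target)
            if poco.complete:
                collection.pocos.append(poco)
                pool[members] = False
            else:
                if emit_partial and poco.loci:
                    collection.pocos.append(poco)
                break
        return collection


def grow_poco(
    dataset: GwasDataset,
    profiles: BinaryProfileSet,
    candidate_pool: Iterable[str] | None = None,
    coverage_fraction: float = 1.0,
) -> PoCo:
    """Grow a single PoCo from the given candidate pool.

    Returns the PoCo; ``poco.complete`` is False if no eligible candidate
    remained before the coverage target was met.
    """
    engine = _GreedyEngine(
        profiles.M,
        dataset.phenotype,
        profiles.locus_ids,
        tie_magnitude=np.abs(
            profiles.D[np.arange(len(profiles.locus_ids)), profiles.model_index - 1]
        ),
    )
    pool = _pool_mask(profiles.locus_ids, candidate_pool)
    target = ceil(coverage_fraction * engine.n1)
    poco, _ = engine.grow(pool, target)
    return poco


def discover_pocos(
    dataset: GwasDataset,
    profiles: BinaryProfileSet,
    coverage_fraction: float = 1.0,
    emit_partial: bool = False,
    reach: np.ndarray | None = None,
    candidate_pool: Iterable[str] | None = None,
) -> PoCoCollection:
    """Discover all disjoint PoCos (network-free unless ``reach`` is given).

    ``reach`` is an optional boolean locus-by-locus reachability matrix;
    when present, every locus after the first of each set must be reachable
    from a previously added one (the network-constrained search).
    """
    engine = _GreedyEngine(
        profiles.M,
        dataset.phenotype,
        profiles.locus_ids,
        tie_magnitude=np.abs(
            profiles.D[np.arange(len(profiles.locus_ids)), profiles.model_index - 1]
        ),
        reach=reach,
    )
    pool = _pool_mask(profiles.locus_ids, candidate_pool)
    return engine.discover(pool, coverage_fraction, emit_partial)


def _pool_mask(locus_ids: Sequence[str], pool: Iterable[str] | None) -> np.ndarray:
    if pool is None:
        return np.ones(len(locus_ids), dtype=bool)
    wanted = set(pool)
    return np.array([lid in wanted for lid in locus_ids], dtype=bool)


def replay_trace(
    poco: PoCo,
    profiles: BinaryProfileSet,
    phenotype: np.ndarray,
    pool: Iterable[str] | None = None,
) -> bool:
    """Check that each traced addition attained the maximal delta.

    Recomputes delta over the full candidate pool at every step of the
    recorded trace and verifies the chosen locus was among the maximizers.
    """
    phenotype = np.asarray(phenotype)
    n1 = int((phenotype == 1).sum())
    n0 = int((phenotype == 0).sum())
    idx = {lid: i for i, lid in enumerate(profiles.locus_ids)}
    pool_mask = _pool_mask(profiles.locus_ids, pool)
    covered = np.zeros(profiles.M.shape[1], dtype=bool)
    for lid, recorded_delta in poco.trace:
        unc = ~covered
        newc = (profiles.M[:, unc & (phenotype == 1)]).sum(axis=1)
        newt = (profiles.M[:, unc & (phenotype == 0)]).sum(axis=1)
        d = newc / n1 - newt / n0
        eligible = pool_mask & (newc > 0)
        if not eligible.any():
            return False
        i = idx[lid]
        if not eligible[i]:
            return False
        if d[i] < d[eligible].max() - 1e-12:
            return False
        if abs(d[i] - recorded_delta) > 1e-12:
            return False
        covered |= profiles.M[i]
        pool_mask = pool_mask.copy()
        pool_mask[i] = False
    return True
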