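"""End-to-end typing pipeline and the simulation benchmark.

``type_read_pairs`` (or ``type_sam`` for pre-computed alignments) runs:
align reads against the panel -> build the sparse log-likelihood matrix
-> select the Dirichlet hyperparameter by ELBO and run variational
inference -> convert expected read counts to depths -> call a diplotype
per locus.  ``run_benchmark`` wraps the simulator around that pipeline
and scores calls against the simulated truth at each digit resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alleles import AlleleDatabase
from .alignment import (AlignmentHit, ErrorModel, KmerIndex, ReadLikelihoodMatrix,
                        build_matrix, builtin_align, read_sam_alignments)
from .diplotype import (DepthProfile, DiplotypeCall, call_all_loci,
                        evaluate_accuracy, expected_depths, posterior_table)
from .inference import DirichletMultinomialVB, PosteriorState, PriorConfig
from .simulator import SimulationConfig, simulate_cohort

logger = logging.getLogger("hlavb")

__all__ = ["TypingResult", "type_read_pairs", "type_sam", "run_benchmark"]


@dataclass
class TypingResult:
    """Everything a typing run produces."""

    calls: dict[str, DiplotypeCall]
    state: PosteriorState
    matrix: ReadLikelihoodMatrix
    profile: DepthProfile
    alpha0: float
    alpha0_elbos: dict[float, float]
    n_input_reads: int
    n_dropped_reads: int

    def call_table(self, individual: str = "sample") -> pd.DataFrame:
        rows = []
        for locus in sorted(self.calls):
            c = self.calls[locus]
            a = [str(n) for n in c.alleles] + ["", ""]
            d = list(c.depths) + [np.nan, np.nan]
            rows.append({
                "individual": individual, "locus": locus,
                "allele1": a[0], "allele2": a[1], "zygosity": c.zygosity,
                "depth1": d[0], "depth2": d[1], "threshold": c.threshold,
            })
        return pd.DataFrame(rows)

    def posterior_frame(self, db: AlleleDatabase) -> pd.DataFrame:
        return posterior_table(self.state.r_hat, self.state.theta_mean,
                               self.profile, db)


def _type_from_hits(
    db: AlleleDatabase,
    hits: Sequence[AlignmentHit],
    n_input_reads: int | None,
    *,
    sample_mean_depth: float,
    prior: PriorConfig,
    error_model: ErrorModel,
    threshold_fraction: float,
    bases_per_fragment: int | None,
    paired: bool,
) -> TypingResult:
    if not hits:
        raise ValueError("no read has any alignment to the panel")
    matrix = build_matrix(hits, db, error_model, paired=paired)
    if bases_per_fragment is None:
        # sequenced bases per pair inferred from observed mate lengths
        lens: dict[tuple[str, int], int] = {}
        for h in hits:
            key = (h.read_id, h.mate)
            lens[key] = max(lens.get(key, 0), h.read_length)
        per_read: dict[str, int] = {}
        for (rid, _), L in lens.items():
            per_read[rid] = per_read.get(rid, 0) + L
        bases_per_fragment = int(round(float(np.median(list(per_read.values())))))
    n_dropped = (n_input_reads - matrix.n_reads) if n_input_reads is not None else 0
    est = DirichletMultinomialVB(alpha0=prior.alpha0, alpha0_grid=prior.alpha0_grid,
                                 tol=prior.tol, max_iter=prior.max_iter)
    est.fit(matrix)
    profile = expected_depths(est.r_, db, bases_per_fragment, sample_mean_depth,
                              threshold_fraction)
    calls = call_all_loci(profile, db)
    logger.info(
        "typed %d reads (%d dropped) x %d alleles; alpha0=%g, %d iterations, "
        "converged=%s", matrix.n_reads, n_dropped, matrix.n_alleles,
        est.alpha0_, est.n_iter_, est.converged_,
    )
    return TypingResult(calls=calls, state=est.state_, matrix=matrix,
                        profile=profile, alpha0=est.alpha0_,
                        alpha0_elbos=est.alpha0_elbos_,
                        n_input_reads=n_input_reads or matrix.n_reads,
                        n_dropped_reads=n_dropped)


def type_read_pairs(
    db: AlleleDatabase,
    pairs: Sequence[tuple[str, str | None, str | None]],
    *,
    sample_mean_depth: float,
    prior: PriorConfig = PriorConfig(),
    error_model: ErrorModel = ErrorModel(),
    threshold_fraction: float = 0.2,
    bases_per_fragment: int | None = None,
    k: int = 25,
    max_hits: int = 100,
    index: KmerIndex | None = None,
) -> TypingResult:
    """Type one sample from paired reads using the built-in aligner."""
    hits = builtin_align(pairs, db, k=k, max_hits=max_hits, index=index)
    return _type_from_hits(db, hits, len(pairs), sample_mean_depth=sample_mean_depth,
                           prior=prior, error_model=error_model,
                           threshold_fraction=threshold_fraction,
                           bases_per_fragment=bases_per_fragment, paired=True)


def type_sam(
    db: AlleleDatabase,
    sam_path: str | Path,
    *,
    sample_mean_depth: float,
    prior: PriorConfig = PriorConfig(),
    error_model: ErrorModel = ErrorModel(),
    threshold_fraction: float = 0.2,
    bases_per_fragment: int | None = None,
    paired: bool = True,
) -> TypingResult:
    """Type one sample from pre-computed multi-mapping SAM/BAM alignments."""
    hits = read_sam_alignments(sam_path, db)
    return _type_from_hits(db, hits, None, sample_mean_depth=sample_mean_depth,
                           prior=prior, error_model=error_model,
                           threshold_fraction=threshold_fraction,
                           bases_per_fragment=bases_per_fragment, paired=paired)


def run_benchmark(
    db: AlleleDatabase,
    n_individuals: int,
    coverages: Sequence[float] = (5.0, 10.0, 20.0, 30.0),
    digits: Sequence[int] = (2, 4, 6, 8),
    seed: int = 0,
    sim_kwargs: dict | None = None,
    prior: PriorConfig = PriorConfig(),
    error_model: ErrorModel = ErrorModel(),
    threshold_fraction: float = 0.2,
    k: int = 25,
    max_hits: int = 100,
) -> pd.DataFrame:
    """Simulate, type and score a cohort at each coverage.

    Returns a tidy table with columns coverage, digits, accuracy,
    true_positives, total, n_individuals, n_failed.  A failed individual
    (e.g. no aligned reads) is recorded and scored as uncalled, not
    fatal.
    """
    sim_kwargs = dict(sim_kwargs or {})
    index = KmerIndex(db, k=k)
    rows = []
    root = np.random.SeedSequence(seed)
    cov_seeds = root.generate_state(len(coverages))
    for cov, cov_seed in zip(coverages, cov_seeds):
        cfg = SimulationConfig(n_individuals=n_individuals, coverage=float(cov),
                               seed=int(cov_seed) % (2**31), **sim_kwargs)
        calls = []
        truths = []
        n_failed = 0
        for ind in simulate_cohort(db, cfg):
            truths.append(ind.truth)
            try:
                res = type_read_pairs(
                    db, ind.reads, sample_mean_depth=cov, prior=prior,
                    error_model=error_model, threshold_fraction=threshold_fraction,
                    bases_per_fragment=2 * cfg.read_len, k=k, max_hits=max_hits,
                    index=index,
                )
                calls.append(res.calls)
            except Exception:
                logger.exception("typing failed for %s at %gx", ind.individual_id, cov)
                n_failed += 1
                from .diplotype import DiplotypeCall

                calls.append({locus: DiplotypeCall(locus, (), "no_call", (), 1.0)
                              for locus in ind.truth})
        for dg in digits:
            acc, table = evaluate_accuracy(calls, truths, dg)
            rows.append({
                "coverage": float(cov), "digits": int(dg), "accuracy": acc,
                "true_positives": int(table["true_positives"].sum()),
                "total": int(table["total"].sum()),
                "n_individuals": n_individuals, "n_failed": n_failed,
            })
    return pd.DataFrame(rows)
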