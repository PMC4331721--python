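"""Diplotype calling from posterior read abundances, and accuracy scoring.

After inference, each allele t carries an expected read-pair count
r_hat[t].  Dividing the implied sequenced bases by the allele length
gives a depth of coverage; a locus diplotype is then decided by the
depth-threshold rules: alleles below 20% of the sample's mean coverage
are ignored, a lone passing allele at >= twice the threshold is a
homozygote, and among several passing alleles the top one is homozygous
only if it exceeds twice the runner-up's depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alleles import AlleleDatabase, AlleleName, match_at_resolution

__all__ = [
    "DepthProfile",
    "DiplotypeCall",
    "expected_depths",
    "call_diplotype",
    "call_all_loci",
    "evaluate_accuracy",
]

ZYGOSITIES = ("homozygous", "heterozygous", "heterozygous_single", "no_call")


@dataclass(frozen=True)
class DepthProfile:
    """Per-allele mean depth of coverage and the calling threshold."""

    depths: np.ndarray
    sample_mean_depth: float
    threshold: float

    def __post_init__(self) -> None:
        if np.any(self.depths < 0):
            raise ValueError("depths must be >= 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass(frozen=True)
class DiplotypeCall:
    """Per-locus call: zero, one or two alleles plus zygosity and depths."""

    locus: str
    alleles: tuple[AlleleName, ...]
    zygosity: str
    depths: tuple[float, ...]
    threshold: float

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if (self.zygosity == "no_call") != (len(self.alleles) == 0):
            raise ValueError("no_call if and only if zero alleles")
        if self.zygosity == "homozygous" and (
            len(self.alleles) != 2 or self.alleles[0] != self.alleles[1]
        ):
            raise ValueError("homozygous calls carry the same allele twice")


def expected_depths(
    r_hat: np.ndarray,
    db: AlleleDatabase,
    bases_per_fragment: int,
    sample_mean_depth: float,
    threshold_fraction: float = 0.2,
) -> DepthProfile:
    """Depth of coverage per allele from expected read-pair counts.

    depth(t) = r_hat[t] * bases_per_fragment / length(t), where
    bases_per_fragment is the sequenced bases per read pair (200 for
    2 x 100 bp).  The calling threshold is threshold_fraction times the
    experiment's genome-wide mean depth (20% of 30x = 6x).
    """
    if bases_per_fragment <= 0:
        raise ValueError("bases_per_fragment must be positive")
    if sample_mean_depth <= 0:
        raise ValueError("sample_mean_depth must be positive")
    r_hat = np.asarray(r_hat, dtype=float)
    lengths = np.asarray(db.lengths(), dtype=float)
    if r_hat.shape != lengths.shape:
        raise ValueError("r_hat length does not match panel size")
    return DepthProfile(
        depths=r_hat * bases_per_fragment / lengths,
        sample_mean_depth=float(sample_mean_depth),
        threshold=threshold_fraction * float(sample_mean_depth),
    )


def call_diplotype(profile: DepthProfile, locus: str, db: AlleleDatabase) -> DiplotypeCall:
    """Apply the three-branch depth rule at one locus.

    (i) no allele reaches the threshold: no call.  (ii) one allele
    passes: homozygous if its depth is at least twice the threshold,
    otherwise a single heterozygous allele.  (iii) two or more pass:
    sort by depth (ties by allele name); the top allele is homozygous if
    its depth is more than twice the second's, otherwise the top two
    form the diplotype.
    """
    if locus not in db.by_locus:
        raise KeyError(f"locus {locus!r} not in panel")
    thr = profile.threshold
    passing = [(t, float(profile.depths[t])) for t in db.by_locus[locus]
               if profile.depths[t] >= thr]
    passing.sort(key=lambda td: (-td[1], str(db.records[td[0]].name)))
    if not passing:
        return DiplotypeCall(locus, (), "no_call", (), thr)
    if len(passing) == 1:
        t, d = passing[0]
        name = db.records[t].name
        if d >= 2.0 * thr:
            return DiplotypeCall(locus, (name, name), "homozygous", (d, d), thr)
        return DiplotypeCall(locus, (name,), "heterozygous_single", (d,), thr)
    (t1, d1), (t2, d2) = passing[0], passing[1]
    n1, n2 = db.records[t1].name, db.records[t2].name
    if d1 > 2.0 * d2:
        return DiplotypeCall(locus, (n1, n1), "homozygous", (d1, d1), thr)
    return DiplotypeCall(locus, (n1, n2), "heterozygous", (d1, d2), thr)


def call_all_loci(profile: DepthProfile, db: AlleleDatabase) -> dict[str, DiplotypeCall]:
    return {locus: call_diplotype(profile, locus, db) for locus in db.by_locus}


def _pair_matches(pred: Sequence[AlleleName], truth: Sequence[AlleleName],
                  digits: int) -> int:
    """Best bipartite matching of <=2 predicted against 2 true alleles."""
    if not pred:
        return 0
    m = lambda a, b: match_at_resolution(a, b, digits)
    if len(pred) == 1:
        return int(m(pred[0], truth[0]) or m(pred[0], truth[1]))
    straight = int(m(pred[0], truth[0])) + int(m(pred[1], truth[1]))
    crossed = int(m(pred[0], truth[1])) + int(m(pred[1], truth[0]))
    return max(straight, crossed)


def evaluate_accuracy(
    calls: Sequence[Mapping[str, DiplotypeCall]],
    truth: Sequence[Mapping[str, tuple[AlleleName, AlleleName]]],
    digits: int,
) -> tuple[float, pd.DataFrame]:
    """Typing accuracy at a digit resolution.

    ``calls[i]`` and ``truth[i]`` map locus -> call / true allele pair
    for individual i.  Per locus the two predicted alleles are matched
    against the two true alleles (order-free); accuracy is matched
    alleles over all true alleles.  Missing predictions (no_call, single
    heterozygous) count their empty slots as misses.  Returns the
    overall accuracy and a per-locus table.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must have the same number of individuals")
    tp: dict[str, int] = {}
    total: dict[str, int] = {}
    for call_map, truth_map in zip(calls, truth):
        if set(call_map) != set(truth_map):
            raise ValueError(
                f"locus sets differ between calls ({sorted(call_map)}) "
                f"and truth ({sorted(truth_map)})"
            )
        for locus, (t1, t2) in truth_map.items():
            matched = _pair_matches(call_map[locus].alleles, (t1, t2), digits)
            tp[locus] = tp.get(locus, 0) + matched
            total[locus] = total.get(locus, 0) + 2
    rows = [
        {"locus": locus, "true_positives": tp[locus], "total": total[locus],
         "accuracy": tp[locus] / total[locus]}
        for locus in sorted(total)
    ]
    table = pd.DataFrame(rows, columns=["locus", "true_positives", "total", "accuracy"])
    overall = sum(tp.values()) / sum(total.values()) if total else float("nan")
    return overall, table


def posterior_table(r_hat: np.ndarray, theta_mean: np.ndarray,
                    profile: DepthProfile, db: AlleleDatabase) -> pd.DataFrame:
    """Per-allele posterior summary: expected reads, abundance, depth."""
    return pd.DataFrame({
        "allele": [str(rec.name) for rec in db.records],
        "locus": [rec.name.locus for rec in db.records],
        "length": db.lengths(),
        "expected_reads": np.asarray(r_hat, dtype=float),
        "theta_mean": np.asarray(theta_mean, dtype=float),
        "depth": profile.depths,
    })
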