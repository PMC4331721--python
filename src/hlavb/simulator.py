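"""Benchmark simulator: synthetic panels, diplotypes and sequencing reads.

Emulates the simulation protocol used to benchmark the typing method:
per-individual diplotypes drawn uniformly from the panel, one SNP per
1,000 bp of individual variation injected into each haplotype copy,
100 bp paired-end reads at a chosen mean coverage with fragment lengths
N(300, 40^2), and 0.1% substitution / deletion / insertion errors per
sequenced base.

A fully synthetic panel generator is also provided so that tests and
benchmarks need no external allele database: alleles are named with HLA
nomenclature (``L1*01:01:01:01`` ...) and constructed on a mutation
hierarchy with disjoint position pools, so that pairwise sequence
distance respects the naming hierarchy (8-digit siblings differ by two
substitutions, 2-digit groups by the coding-scale divergence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .alleles import AlleleDatabase, AlleleName, AlleleRecord
from .alignment import revcomp

__all__ = [
    "SimulationConfig",
    "SimulatedIndividual",
    "generate_synthetic_panel",
    "sample_diplotypes",
    "inject_snps",
    "simulate_reads",
    "simulate_individual",
    "simulate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Benchmark conditions for read simulation.

    Defaults are the benchmark protocol: 100 bp paired ends, fragment
    length N(300, 40^2) bp, 1 SNP per kb of individual variation, and
    0.1% substitution/deletion/insertion error per sequenced base.
    Coverage is the mean depth in x over the individual's haplotypes.
    """

    n_individuals: int
    coverage: float = 30.0
    read_len: int = 100
    frag_mean: float = 300.0
    frag_sd: float = 40.0
    snp_rate: float = 0.001
    err_sub: float = 0.001
    err_del: float = 0.001
    err_ins: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "err_sub", "err_del", "err_ins"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0,1), got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.frag_mean < self.read_len:
            raise ValueError("frag_mean must be >= read_len")


@dataclass
class SimulatedIndividual:
    """Truth diplotypes, mutated haplotypes and simulated read pairs."""

    individual_id: str
    truth: dict[str, tuple[AlleleName, AlleleName]]
    haplotypes: list[tuple[str, str]]  # (haplotype id, sequence)
    snp_positions: dict[str, list[int]]
    reads: list[tuple[str, str, str]]  # (read id, mate1 seq, mate2 seq)


# ---------------------------------------------------------------------------
# Synthetic allele panel
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_positions(seq: np.ndarray, positions: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def generate_synthetic_panel(
    n_loci: int = 6,
    alleles_per_locus: int = 12,
    length: int = 1000,
    divergence: float = 0.02,
    hierarchy: tuple[int, int, int, int] = (3, 2, 1, 2),
    seed: int = 0,
) -> AlleleDatabase:
    """Generate a hierarchically structured allele panel.

    ``hierarchy`` gives the branching factor at each nomenclature level
    (2-digit groups, 4-digit proteins, 6-digit, 8-digit); its product
    must equal ``alleles_per_locus``.  Substitution counts per level are
    ``round(length * divergence)`` for 2-digit groups, a quarter of that
    for 4-digit, 3 for 6-digit and 1 per 8-digit sibling, each drawn
    from disjoint position pools so that alleles with more shared name
    fields are strictly closer in Hamming distance.  Deterministic per
    seed.
    """
    if not 0.0 < divergence <= 0.2:
        raise ValueError(f"divergence must be in (0, 0.2], got {divergence}")
    if math.prod(hierarchy) != alleles_per_locus:
        raise ValueError(
            f"hierarchy {hierarchy} implies {math.prod(hierarchy)} alleles per "
            f"locus, expected {alleles_per_locus}"
        )
    level_subs = (max(1, round(length * divergence)),
                  max(2, round(length * divergence / 4)), 3, 1)
    # positions consumed by one allele's lineage and by all its relatives
    g1, g2, g3, g4 = hierarchy
    needed = (g1 * level_subs[0] + g1 * g2 * level_subs[1]
              + g1 * g2 * g3 * level_subs[2] + alleles_per_locus * level_subs[3])
    if needed > length:
        raise ValueError(
            f"panel parameters need {needed} distinct substitution positions "
            f"but alleles are only {length} bp"
        )
    rng = np.random.default_rng(seed)
    records: list[AlleleRecord] = []
    for li in range(1, n_loci + 1):
        base = _random_dna(rng, length)
        pool = rng.permutation(length)
        cursor = 0

        def take(n: int) -> np.ndarray:
            nonlocal cursor
            out = pool[cursor : cursor + n]
            cursor += n
            return out

        for a in range(1, g1 + 1):
            seq_a = _mutate_positions(base, take(level_subs[0]), rng)
            for b in range(1, g2 + 1):
                seq_b = _mutate_positions(seq_a, take(level_subs[1]), rng)
                for c in range(1, g3 + 1):
                    seq_c = _mutate_positions(seq_b, take(level_subs[2]), rng)
                    for d in range(1, g4 + 1):
                        seq_d = _mutate_positions(seq_c, take(level_subs[3]), rng)
                        name = AlleleName(
                            locus=f"L{li}",
                            fields=(f"{a:02d}", f"{b:02d}", f"{c:02d}", f"{d:02d}"),
                            raw=f"L{li}*{a:02d}:{b:02d}:{c:02d}:{d:02d}",
                        )
                        records.append(AlleleRecord(name=name,
                                                    sequence=seq_d.tobytes().decode()))
    db = AlleleDatabase(records=records)
    seqs = {rec.sequence for rec in records}
    if len(seqs) != len(records):  # disjoint pools make this unreachable
        raise RuntimeError("synthetic panel produced duplicate sequences")
    return db


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------


def sample_diplotypes(
    db: AlleleDatabase,
    rng: np.random.Generator,
    loci: Sequence[str] | None = None,
) -> dict[str, tuple[int, int]]:
    """Two independent uniform allele draws (with replacement) per locus.

    Returns record indices; homozygous draws are possible.
    """
    loci = list(db.by_locus) if loci is None else list(loci)
    out: dict[str, tuple[int, int]] = {}
    for locus in loci:
        if locus not in db.by_locus:
            raise KeyError(f"locus {locus!r} not in panel")
        idxs = db.by_locus[locus]
        out[locus] = (idxs[rng.integers(len(idxs))], idxs[rng.integers(len(idxs))])
    return out


def inject_snps(sequence: str, rate: float,
                rng: np.random.Generator) -> tuple[str, list[int]]:
    """Mutate each position independently with probability ``rate``.

    Each SNP substitutes a uniformly chosen different base.  Returns the
    mutated sequence and the SNP positions for truth tracking.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0,1), got {rate}")
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    if rate == 0.0:
        return sequence, []
    mask = rng.random(arr.size) < rate
    positions = np.flatnonzero(mask)
    for p in positions:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode(), positions.tolist()


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def _sequence_bases(template: str, start: int, read_len: int, cfg: SimulationConfig,
                    rng: np.random.Generator) -> str:
    """Emit read_len bases from template[start:], applying per-base errors.

    A deletion drops the template base and pulls the next one; an
    insertion emits a random base without consuming the template.
    """
    p_ins, p_del, p_sub = cfg.err_ins, cfg.err_del, cfg.err_sub
    if p_ins == 0.0 and p_del == 0.0 and p_sub == 0.0:
        return template[start : start + read_len]
    out = []
    i = start
    limit = len(template)
    while len(out) < read_len:
        if i >= limit:
            out.append(chr(_BASES[rng.integers(4)]))  # template exhausted
            continue
        u = rng.random()
        if u < p_ins:
            out.append(chr(_BASES[rng.integers(4)]))
        elif u < p_ins + p_del:
            i += 1
        elif u < p_ins + p_del + p_sub:
            b = template[i]
            choices = [c for c in "ACGT" if c != b] or ["A"]
            out.append(choices[rng.integers(len(choices))])
            i += 1
        else:
            out.append(template[i])
            i += 1
    return "".join(out)


def simulate_reads(
    haplotypes: Sequence[tuple[str, str]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    individual_id: str = "sim",
) -> list[tuple[str, str, str]]:
    """Paired-end reads over an individual's haplotypes.

    The pair count is round(coverage * total haplotype length /
    (2 * read_len)); each pair draws its source haplotype in proportion
    to length, a fragment length from the truncated normal, and a
    uniform start.  Mate 2 is the reverse complement of the fragment's
    far end.  Read names encode the source haplotype and position.
    """
    usable = [(hid, seq) for hid, seq in haplotypes if len(seq) >= cfg.read_len]
    if len(usable) < len(haplotypes):
        import warnings

        warnings.warn("haplotypes shorter than read_len were skipped")
    if not usable:
        return []
    lengths = np.array([len(s) for _, s in usable], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(cfg.coverage * total / (2.0 * cfg.read_len)))
    probs = lengths / total
    sources = rng.choice(len(usable), size=n_pairs, p=probs)
    reads: list[tuple[str, str, str]] = []
    for j in range(n_pairs):
        hid, seq = usable[sources[j]]
        hap_len = len(seq)
        frag = None
        for _ in range(100):
            f = int(round(rng.normal(cfg.frag_mean, cfg.frag_sd)))
            if cfg.read_len <= f <= hap_len:
                frag = f
                break
        if frag is None:
            frag = min(hap_len, max(cfg.read_len, int(cfg.frag_mean)))
        start = int(rng.integers(0, hap_len - frag + 1))
        mate1 = _sequence_bases(seq, start, cfg.read_len, cfg, rng)
        # far end, reverse strand: template runs from fragment end inward
        rc = revcomp(seq)
        rc_start = hap_len - (start + frag)
        mate2 = _sequence_bases(rc, rc_start, cfg.read_len, cfg, rng)
        read_id = f"{individual_id}:p{j}:{hid}:{start}:{frag}"
        reads.append((read_id, mate1, mate2))
    return reads


def simulate_individual(
    db: AlleleDatabase,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    individual_id: str = "ind0",
    loci: Sequence[str] | None = None,
) -> SimulatedIndividual:
    """One individual: draw diplotypes, inject SNPs, simulate reads."""
    dip = sample_diplotypes(db, rng, loci=loci)
    truth: dict[str, tuple[AlleleName, AlleleName]] = {}
    haplotypes: list[tuple[str, str]] = []
    snp_positions: dict[str, list[int]] = {}
    for locus, (i1, i2) in dip.items():
        truth[locus] = (db.records[i1].name, db.records[i2].name)
        for copy_no, idx in enumerate((i1, i2), start=1):
            rec = db.records[idx]
            hap_id = f"{rec.name}|h{copy_no}"
            seq, pos = inject_snps(rec.sequence, cfg.snp_rate, rng)
            haplotypes.append((hap_id, seq))
            snp_positions[hap_id] = pos
    reads = simulate_reads(haplotypes, cfg, rng, individual_id=individual_id)
    return SimulatedIndividual(individual_id=individual_id, truth=truth,
                               haplotypes=haplotypes, snp_positions=snp_positions,
                               reads=reads)


def simulate_cohort(
    db: AlleleDatabase,
    cfg: SimulationConfig,
    loci: Sequence[str] | None = None,
) -> Iterator[SimulatedIndividual]:
    """Independent individuals on child RNG streams of ``cfg.seed``."""
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_individuals)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        yield simulate_individual(db, cfg, rng, individual_id=f"ind{i}", loci=loci)


def write_fastq(reads: Sequence[tuple[str, str, str]], path1: str | Path,
                path2: str | Path) -> None:
    """Write paired reads as two FASTQ files with constant 'I' qualities."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for read_id, m1, m2 in reads:
            f1.write(f"@{read_id}\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{read_id}\n{m2}\n+\n{'I' * len(m2)}\n")
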