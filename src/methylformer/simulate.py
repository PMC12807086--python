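"""Seeded nanopore-signal simulator with k-mer levels and methylation shifts.

The simulator emulates the statistical structure the caller relies on: the
ionic current of each event is set by the k bases occupying the pore
(default k = 7), and 5mC at a CpG shifts the current of the methylated
event and, with a triangular taper, of its neighbours across the pore span.

The clean level of a k-mer is a deterministic, seeded map with marginal
distribution N(0, level_scale^2), decomposed as an additive per-position,
per-base component (``additive_fraction`` of the variance, default 0.75)
plus an independent per-k-mer Gaussian residual.  Pore chemistry is close to
additive in the neighbouring bases, and the additive part is what lets a
trained model generalize context-dependent baselines to unseen sites; the
residual keeps each k-mer idiosyncratic.  Raw samples are emitted on an
arbitrary current scale (offset 90, unit level scale), pre-normalization, so
the pipeline's per-read median/MAD standardization is exercised end to end.

Every draw comes from one seeded generator in a fixed order, so all outputs
are byte-reproducible for a given config.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .features import find_cpg_candidates
from .io import Event, LabeledSite
from .summary import SiteSummary

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimConfig:
    """Study conditions for one simulated run.

    ``delta`` is the methylation shift at the methylated event in level
    units; ``shift_span`` events centred on the CpG cytosine receive the
    shift with a triangular taper (weight 1 at the centre, decaying
    linearly; default span = k).  ``site_meth_prob`` is the per-CpG-site
    probability of being methylated and ``read_meth_fidelity`` the
    probability a read copy agrees with its site's status.  ``dwell_mean``
    is the mean number of raw samples per event (shifted Poisson, >= 1).
    """

    genome_length: int = 20_000
    n_reads: int = 40
    read_length: int = 1_000
    k: int = 7
    level_scale: float = 1.0
    noise_sd: float = 0.3
    delta: float = 0.6
    shift_span: Optional[int] = None
    site_meth_prob: float = 0.5
    read_meth_fidelity: float = 1.0
    dwell_mean: float = 8.0
    seed: int = 0
    pore_seed: Optional[int] = None
    emit_minus_strand: bool = False
    additive_fraction: float = 0.75
    signal_offset: float = 90.0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.shift_span is None:
            self.shift_span = self.k
        if self.k % 2 == 0 or self.k < 1 or self.k > 9:
            raise ValueError("k must be an odd integer in [1, 9]")
        for name in ("site_meth_prob", "read_meth_fidelity", "additive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        if self.genome_length < self.read_length:
            raise ValueError("genome shorter than read_length")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def resolved_pore_seed(self) -> int:
        return self.seed if self.pore_seed is None else self.pore_seed


class LevelModel:
    """Deterministic seeded map from k-mers to clean current levels."""

    def __init__(self, k: int, level_scale: float, additive_fraction: float,
                 rng: np.random.Generator):
        self.k = k
        self.level_scale = level_scale
        add_sd = level_scale * np.sqrt(additive_fraction / k)
        res_sd = level_scale * np.sqrt(1.0 - additive_fraction)
        # draws in fixed order for byte-reproducibility; per-position rows are
        # centred over the four bases (inflated by sqrt(4/3) so the marginal
        # variance is preserved), otherwise each seed would carry a random
        # genome-wide current offset
        additive = rng.normal(0.0, 1.0, size=(k, 4))
        additive -= additive.mean(axis=1, keepdims=True)
        realized = float(np.sum(additive**2) / 4.0)  # var under uniform bases
        if realized > 0 and additive_fraction > 0:
            additive *= np.sqrt(additive_fraction) * level_scale / np.sqrt(realized)
        self.additive = additive
        residual = rng.normal(0.0, 1.0, size=4 ** k)
        residual -= residual.mean()
        sd = residual.std()
        if sd > 0:
            residual *= res_sd / sd
        self.residual = residual

    def _codes(self, base_idx: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Per-position k-mer codes and additive sums for an int-encoded sequence.

        The sequence is virtually padded with 'A' so every position has a
        full k-mer context.
        """
        k, half = self.k, self.k // 2
        padded = np.concatenate(
            [np.zeros(half, dtype=int), base_idx, np.zeros(half, dtype=int)]
        )
        n = base_idx.size
        codes = np.zeros(n, dtype=np.int64)
        additive = np.zeros(n)
        for j in range(k):
            col = padded[j : j + n]
            codes = codes * 4 + col
            additive += self.additive[j, col]
        return codes, additive

    def sequence_levels(self, sequence: str) -> np.ndarray:
        """Clean (unmethylated) level at every position of a sequence."""
        base_idx = _encode(sequence)
        codes, additive = self._codes(base_idx)
        return additive + self.residual[codes]

    def level(self, kmer: str) -> float:
        """Clean level of one k-mer — a pure function of (k-mer, seed)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        return float(self.sequence_levels(kmer)[self.k // 2])


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=int)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    return out


def _taper_weights(span: int) -> np.ndarray:
    """Triangular taper over `span` events centred on the methylated C."""
    half = span // 2
    offsets = np.arange(-half, span - half)
    return 1.0 - np.abs(offsets) / (half + 1.0)


@dataclass
class SimResult:
    """All outputs of one simulation, mutually consistent by construction."""

    config: SimConfig
    genome: str
    events_by_read: Dict[str, List[Event]]
    labels: List[LabeledSite]
    site_status: pd.DataFrame  # chrom, pos, strand, status
    truth: List[SiteSummary]  # realized per-site coverage / methylated reads
    level_model: LevelModel

    def write(self, prefix: str | os.PathLike) -> Dict[str, str]:
        """Write reference FASTA, event table, labels, truth bedMethyl and
        the observed-k-mer level table; returns the paths."""
        prefix = os.fspath(prefix)
        paths = {
            "reference": prefix + ".fa",
            "events": prefix + ".events.tsv",
            "labels": prefix + ".labels.tsv",
            "truth": prefix + ".truth.bed",
            "levels": prefix + ".levels.tsv",
        }
        mio.write_fasta({self.config.chrom: self.genome}, paths["reference"])
        mio.write_event_table(self.events_by_read, paths["events"])
        mio.write_labels(self.labels, paths["labels"])
        mio.write_bedmethyl(self.truth, paths["truth"])
        self._write_levels(paths["levels"])
        return paths

    def _write_levels(self, path: str) -> None:
        k, half = self.config.k, self.config.k // 2
        padded = "A" * half + self.genome + "A" * half
        kmers = sorted({padded[p : p + k] for p in range(len(self.genome))})
        with open(path, "w") as fh:
            for kmer in kmers:
                fh.write(f"{kmer}\t{self.level_model.level(kmer):.6f}\n")


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a reference, reads with signal events, labels and truth."""
    # separate streams: the pore's level map is independent of the genome
    # and read draws, so runs can share chemistry via pore_seed
    rng = np.random.default_rng([cfg.seed, 1])
    pore_rng = np.random.default_rng([cfg.resolved_pore_seed, 0])
    G, L = cfg.genome_length, cfg.read_length
    genome_idx = rng.integers(0, 4, size=G)
    genome = "".join(BASES[i] for i in genome_idx)

    level_model = LevelModel(cfg.k, cfg.level_scale, cfg.additive_fraction, pore_rng)
    base_levels = level_model.sequence_levels(genome)

    fwd_cpg = np.array(find_cpg_candidates(genome, "forward"), dtype=int)
    fwd_status = rng.random(fwd_cpg.size) < cfg.site_meth_prob
    status_by_site: Dict[Tuple[int, str], bool] = {
        (int(p), "+"): bool(s) for p, s in zip(fwd_cpg, fwd_status)
    }
    site_rows = [(int(p), "+", int(s)) for p, s in zip(fwd_cpg, fwd_status)]
    minus_levels = None
    if cfg.emit_minus_strand:
        # palindromic partner cytosines, anchored at p + 1 on the minus strand
        minus_status = rng.random(fwd_cpg.size) < cfg.site_meth_prob
        for p, s in zip(fwd_cpg, minus_status):
            status_by_site[(int(p) + 1, "-")] = bool(s)
            site_rows.append((int(p) + 1, "-", int(s)))
        rc = genome.translate(_COMPLEMENT)[::-1]
        # minus_levels[p] = clean level of the minus-strand k-mer centred at p
        minus_levels = level_model.sequence_levels(rc)[::-1].copy()

    taper = _taper_weights(cfg.shift_span)
    half_span = cfg.shift_span // 2

    starts = rng.integers(0, G - L + 1, size=cfg.n_reads)
    if cfg.emit_minus_strand:
        strands = np.where(rng.random(cfg.n_reads) < 0.5, "+", "-")
    else:
        strands = np.full(cfg.n_reads, "+")
    events_by_read: Dict[str, List[Event]] = {}
    labels: List[LabeledSite] = []
    truth_counts: Dict[Tuple[int, str], List[int]] = {}

    site_pos = {
        strand: np.array(sorted(p for p, s in status_by_site if s == strand), dtype=int)
        for strand in ("+", "-")
    }

    for r, (start, strand) in enumerate(zip(starts, strands)):
        read_id = f"read{r:05d}"
        if strand == "+":
            levels = base_levels[start : start + L].copy()
        else:
            levels = minus_levels[start : start + L].copy()
        positions = site_pos[strand]
        in_read = positions[(positions >= start) & (positions < start + L)]
        read_site_labels = []
        for pos in in_read:
            status = status_by_site[(int(pos), strand)]
            agree = rng.random() < cfg.read_meth_fidelity
            label = int(status) if agree else 1 - int(status)
            read_site_labels.append((int(pos), label))
            if label == 1 and cfg.delta > 0:
                lo = max(0, pos - start - half_span)
                hi = min(L, pos - start - half_span + cfg.shift_span)
                t_lo = lo - (pos - start - half_span)
                levels[lo:hi] += cfg.delta * taper[t_lo : t_lo + hi - lo]
            truth_counts.setdefault((int(pos), strand), []).append(label)

        counts = 1 + rng.poisson(cfg.dwell_mean - 1.0, size=L)
        noise = rng.normal(0.0, cfg.noise_sd, size=int(counts.sum()))
        bounds = np.concatenate([[0], np.cumsum(counts)])
        events = []
        for i in range(L):
            base = genome[start + i]
            if strand == "-":
                base = base.translate(_COMPLEMENT)
            samples = (
                cfg.signal_offset + levels[i] + noise[bounds[i] : bounds[i + 1]]
            )
            events.append(
                Event(
                    read_id=read_id,
                    chrom=cfg.chrom,
                    strand=strand,
                    ref_pos=int(start + i),
                    ref_base=base,
                    samples=samples,
                )
            )
        events_by_read[read_id] = events
        for pos, label in read_site_labels:
            labels.append(LabeledSite(read_id, cfg.chrom, strand, pos, label))

    site_rows.sort()
    site_df = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": [p for p, _, _ in site_rows],
            "strand": [s for _, s, _ in site_rows],
            "status": [v for _, _, v in site_rows],
        }
    )
    truth = [
        SiteSummary(
            chrom=cfg.chrom,
            pos=pos,
            strand=strand,
            coverage=len(lab),
            methylated_count=int(sum(lab)),
        )
        for (pos, strand), lab in sorted(truth_counts.items())
    ]
    return SimResult(
        config=cfg,
        genome=genome,
        events_by_read=events_by_read,
        labels=labels,
        site_status=site_df,
        truth=truth,
        level_model=level_model,
    )


def truth_coverage_report(result: SimResult, window: int = 21) -> pd.DataFrame:
    """Per-CpG-site count of reads providing full window context.

    A read contributes iff the site lies at least ``⌊window/2⌋`` events from
    both read ends, i.e. the site would yield a feature window.
    """
    half = window // 2
    counts: Dict[Tuple[int, str], int] = {
        (int(p), s): 0
        for p, s in zip(result.site_status["pos"], result.site_status["strand"])
    }
    for events in result.events_by_read.values():
        if not events:
            continue
        start = events[0].ref_pos
        end = events[-1].ref_pos
        strand = events[0].strand
        for pos, s in counts:
            if s == strand and start + half <= pos <= end - half:
                counts[(pos, s)] += 1
    keys = sorted(counts)
    return pd.DataFrame(
        {
            "chrom": result.config.chrom,
            "pos": [p for p, _ in keys],
            "strand": [s for _, s in keys],
            "coverage": [counts[k] for k in keys],
        }
    )
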