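"""Synthetic barcode-sequencing data with the statistical structure the
analysis assumes.

The generator emulates a barcoded clone library injected into tumors:

* an inoculum of ~40,000 random 20-nt barcodes whose frequencies follow a
  narrow log-normal spread (99% of barcodes within a six-fold range),
* deep amplicon sequencing as multinomial sampling of reads (with technical
  replicates), optionally rendered as FASTQ with the amplicon's
  ACCAA[20-nt]TGTAG anchor structure and substitution errors,
* full in-silico colonization experiments: a binomial bottleneck per tumor
  followed by stochastic consumer-resource growth and multinomial
  sequencing at the sampled days, with ground truth retained.

All randomness derives from one integer seed through named streams
(:mod:`tumorclones.seeding`), so bundles are bit-reproducible.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .bottleneck import apply_bottleneck, founder_counts
from .dynamics import SimulationParams, Trajectory, simulate
from .seeding import stream
from .tables import CountTable

__all__ = [
    "BarcodeLibrary",
    "generate_inoculum",
    "sample_sequencing_counts",
    "generate_reads",
    "write_fastq",
    "extract_barcode_counts",
    "ExperimentBundle",
    "simulate_experiment",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
BARCODE_LENGTH = 20
DEFAULT_UPSTREAM = "ACCAA"
DEFAULT_DOWNSTREAM = "TGTAG"


@dataclass
class BarcodeLibrary:
    """Inoculum barcode identities with relative frequencies.

    ``frequencies`` are strictly positive and sum to 1; ``total_cells`` is
    the number of cells injected, so barcode i contributes about
    ``total_cells * frequencies[i]`` cells to the inoculum.
    """

    barcode_ids: list[str]
    frequencies: np.ndarray
    total_cells: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequencies must be strictly positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1 within 1e-9")
        if len(self.barcode_ids) != f.size:
            raise ValueError("barcode_ids and frequencies must align")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            raise ValueError("barcode_ids must be unique")
        for b in self.barcode_ids[:1000]:
            if len(b) != BARCODE_LENGTH or re.fullmatch("[ACGT]+", b) is None:
                raise ValueError(f"invalid barcode {b!r}: need {BARCODE_LENGTH}-mers over ACGT")
        self.frequencies = f

    def __len__(self) -> int:
        return len(self.barcode_ids)

    def cell_counts(self) -> np.ndarray:
        """Integer inoculum cells per barcode, round(N*f_i)."""
        return founder_counts(self.frequencies, self.total_cells)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"barcode": self.barcode_ids, "frequency": self.frequencies}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, total_cells: float) -> "BarcodeLibrary":
        df = pd.read_csv(path, sep="\t")
        if not {"barcode", "frequency"} <= set(df.columns):
            raise ValueError(f"{path}: need 'barcode' and 'frequency' columns")
        f = df["frequency"].to_numpy(dtype=float)
        return cls(list(df["barcode"]), f / f.sum(), total_cells)


def _random_barcodes(n: int, rng: np.random.Generator, max_attempts: int = 50) -> list[str]:
    if n > 4**BARCODE_LENGTH:
        raise ValueError(f"cannot draw {n} unique {BARCODE_LENGTH}-mers")
    seen: set[str] = set()
    for _ in range(max_attempts):
        need = n - len(seen)
        if need == 0:
            break
        draws = rng.integers(0, 4, size=(need, BARCODE_LENGTH))
        for row in draws:
            seen.add("".join("ACGT"[i] for i in row))
            if len(seen) == n:
                break
    if len(seen) < n:
        raise ValueError(f"failed to draw {n} unique barcodes in {max_attempts} attempts")
    out = sorted(seen)
    rng.shuffle(out)
    return out


def generate_inoculum(
    n_barcodes: int,
    fold_range: float = 6.0,
    central_mass: float = 0.99,
    total_cells: float = 5e6,
    seed: int | np.random.Generator = 0,
) -> BarcodeLibrary:
    """Draw a narrow log-normal inoculum frequency distribution.

    Log-frequencies are normal with sigma = ln(fold_range)/(2*z), where z is
    the (1+central_mass)/2 normal quantile, so the central ``central_mass``
    of barcodes spans a factor ``fold_range`` in frequency; after drawing,
    the log-deviations are rescaled so the empirical quantile ratio equals
    ``fold_range`` exactly. Defaults reproduce the study inoculum: 99% of
    barcodes within a six-fold range.
    """
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    if fold_range <= 1:
        raise ValueError("fold_range must be > 1")
    if not 0 < central_mass < 1:
        raise ValueError("central_mass must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "inoculum")
    ids = _random_barcodes(n_barcodes, rng)
    if n_barcodes == 1:
        return BarcodeLibrary(ids, np.array([1.0]), total_cells)
    z = _stats.norm.ppf(0.5 + central_mass / 2.0)
    sigma = math.log(fold_range) / (2.0 * z)
    logf = rng.normal(0.0, sigma, size=n_barcodes)
    tail = (1.0 - central_mass) / 2.0
    q_lo, q_hi = np.quantile(logf, [tail, 1.0 - tail])
    if q_hi > q_lo:
        logf = logf * (math.log(fold_range) / (q_hi - q_lo))
    f = np.exp(logf)
    return BarcodeLibrary(ids, f / f.sum(), total_cells)


def sample_sequencing_counts(
    frequencies,
    depth: int,
    n_replicates: int = 1,
    seed: int | np.random.Generator = 0,
    barcode_ids: Sequence[str] | None = None,
    sample_name: str = "sample",
) -> CountTable:
    """Multinomial read sampling: each replicate is an independent draw of
    ``depth`` reads from the given frequencies."""
    f = np.asarray(frequencies, dtype=float)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "sequencing")
    if barcode_ids is None:
        barcode_ids = [f"bc{i:06d}" for i in range(f.size)]
    cols = {}
    for k in range(1, n_replicates + 1):
        counts = rng.multinomial(int(depth), f / f.sum()) if depth > 0 else np.zeros(f.size, int)
        cols[f"{sample_name}_rep{k}"] = counts
    return CountTable(pd.DataFrame(cols, index=list(barcode_ids)), units="reads")


# ---------------------------------------------------------------------------
# FASTQ rendering and the simplified extractor
# ---------------------------------------------------------------------------

def generate_reads(
    counts: dict[str, int] | pd.Series,
    upstream_anchor: str = DEFAULT_UPSTREAM,
    downstream_anchor: str = DEFAULT_DOWNSTREAM,
    per_base_error: float = 0.0,
    seed: int | np.random.Generator = 0,
    quality: int = 30,
    read_length: int | None = None,
):
    """Render a count-table column as amplicon reads.

    Each read is ``pad + upstream + barcode + downstream [+ pad]`` with 0-3
    random leading bases (mirroring the amplicon primer's variable offset)
    and i.i.d. substitution errors at ``per_base_error``. Qualities are a
    constant Phred score (default Q30). Yields Bio.SeqRecord objects.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if not upstream_anchor or not downstream_anchor:
        raise ValueError("anchors must be non-empty")
    if re.fullmatch("[ACGT]+", upstream_anchor + downstream_anchor) is None:
        raise ValueError("anchors must be DNA over ACGT")
    if not 0 <= per_base_error < 1:
        raise ValueError("per_base_error must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "reads")
    items = counts.items() if hasattr(counts, "items") else counts
    i = 0
    for barcode, count in items:
        core = upstream_anchor + barcode + downstream_anchor
        for _ in range(int(count)):
            n_pad = int(rng.integers(0, 4))
            pad = "".join("ACGT"[j] for j in rng.integers(0, 4, size=n_pad))
            seq = pad + core
            if read_length is not None and len(seq) < read_length:
                tail = rng.integers(0, 4, size=read_length - len(seq))
                seq = seq + "".join("ACGT"[j] for j in tail)
            if per_base_error > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                hit = rng.random(arr.size) < per_base_error
                if hit.any():
                    # substitute with a uniformly random *different* base
                    orig = arr[hit]
                    lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
                    new = np.array(
                        [lut[o][rng.integers(0, 3)] for o in orig], dtype=np.uint8
                    )
                    arr[hit] = new
                    seq = arr.tobytes().decode()
            rec = SeqRecord(Seq(seq), id=f"read{i}", description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            i += 1
            yield rec


def write_fastq(records: Iterable, path: str | Path) -> int:
    """Write SeqRecords as standard 4-line Phred+33 FASTQ; returns count."""
    from Bio import SeqIO

    return SeqIO.write(records, str(path), "fastq")


def extract_barcode_counts(
    reads,
    upstream_anchor: str = DEFAULT_UPSTREAM,
    downstream_anchor: str = DEFAULT_DOWNSTREAM,
    barcode_length: int = BARCODE_LENGTH,
) -> Counter:
    """Exact-anchor barcode extraction and counting.

    A simplified stand-in for read clustering: reads whose anchors match
    exactly contribute their inner ``barcode_length``-mer to the count;
    anything else is discarded. ``reads`` may be SeqRecords, strings, or a
    FASTQ path.
    """
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        reads = SeqIO.parse(str(reads), "fastq")
    pat = re.compile(
        re.escape(upstream_anchor) + f"([ACGT]{{{barcode_length}}})" + re.escape(downstream_anchor)
    )
    counts: Counter = Counter()
    for r in reads:
        s = str(r.seq) if hasattr(r, "seq") else str(r)
        m = pat.search(s)
        if m:
            counts[m.group(1)] += 1
    return counts


def merge_similar_barcodes(counts: Counter, max_hamming: int = 2) -> Counter:
    """Optional error-collapse: fold each barcode into a more abundant
    neighbor within ``max_hamming`` substitutions (greedy, most-abundant
    first). Quadratic scan; intended for small extracted sets."""
    ordered = [b for b, _ in counts.most_common()]
    merged: Counter = Counter()
    kept: list[str] = []
    for b in ordered:
        target = None
        for k in kept:
            if len(k) == len(b) and sum(x != y for x, y in zip(k, b)) <= max_hamming:
                target = k
                break
        if target is None:
            kept.append(b)
            merged[b] += counts[b]
        else:
            merged[target] += counts[b]
    return merged


# ---------------------------------------------------------------------------
# full in-silico experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentBundle:
    """A complete simulated colonization experiment with ground truth."""

    library: BarcodeLibrary
    founders: np.ndarray                 # (n_tumors, n_barcodes) post-bottleneck cells
    trajectories: list[Trajectory]       # one per tumor (barcodes with >= 1 founder only)
    founder_index: list[np.ndarray]      # per tumor: library indices of its founders
    count_tables: dict[float, CountTable]  # sample day (hr) -> counts per tumor/replicate
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.library.to_tsv(outdir / "inoculum.tsv")
        np.savetxt(outdir / "founders.tsv", self.founders, fmt="%d", delimiter="\t")
        for day, table in self.count_tables.items():
            table.to_tsv(outdir / f"counts_day{day:g}.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def simulate_experiment(
    library: BarcodeLibrary,
    sim_params: SimulationParams,
    q: float,
    n_tumors: int = 1,
    sample_days: Sequence[float] = (24.0,),
    depth: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 2,
) -> ExperimentBundle:
    """Simulate tumors end to end: bottleneck -> growth -> sequencing.

    Per tumor, each barcode's round(N*f_i) inoculum cells pass a binomial
    bottleneck with survival q; surviving founders are integrated under
    ``sim_params`` (horizon = max(sample_days)); at every sample day the
    clone frequencies are sequenced as ``n_replicates`` independent
    multinomial draws of ``depth`` reads. Ground truth (q, parameters,
    per-tumor founder counts) is retained in ``truth``.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    if not sample_days or min(sample_days) <= 0:
        raise ValueError("sample_days must be positive hours")
    base = seed if isinstance(seed, (int, np.integer)) else None
    rng_bottle = stream(base, "experiment", "bottleneck") if base is not None else seed
    sample_days = sorted(float(d) for d in sample_days)
    horizon = sample_days[-1]
    params = sim_params.with_(horizon=horizon)
    inoc_cells = library.cell_counts()

    founders = np.zeros((n_tumors, len(library)), dtype=np.int64)
    trajectories: list[Trajectory] = []
    founder_index: list[np.ndarray] = []
    day_columns: dict[float, dict[str, np.ndarray]] = {d: {} for d in sample_days}

    n_steps = max(1, int(round(horizon / params.dt)))
    day_steps = {d: max(1, int(round(d / params.dt))) for d in sample_days}
    # record at a stride that lands exactly on each sample day
    stride = math.gcd(*day_steps.values()) if len(day_steps) > 1 else day_steps[horizon]
    stride = max(1, min(stride, max(1, n_steps // 200)))
    while any(s % stride for s in day_steps.values()):
        stride -= 1

    for t in range(n_tumors):
        if base is not None:
            rb = stream(base, "experiment", "bottleneck", t)
            rd = stream(base, "experiment", "dynamics", t)
            rs = stream(base, "experiment", "sequencing", t)
        else:
            rb = rd = rs = seed
        surv = apply_bottleneck(inoc_cells, q, rb)
        founders[t] = surv
        idx = np.flatnonzero(surv)
        founder_index.append(idx)
        if idx.size == 0:
            traj = Trajectory(
                times=np.array([0.0, horizon]),
                abundances=np.zeros((2, 0)),
                resource=np.array([params.s0, params.s0]),
                survivors=np.array([0, 0]),
            )
        else:
            traj = simulate(params, surv[idx].astype(float), rd, record_stride=stride)
        trajectories.append(traj)
        for d in sample_days:
            row = np.zeros(len(library))
            if idx.size:
                j = int(np.argmin(np.abs(traj.times - d)))
                row[idx] = traj.abundances[j]
            total = row.sum()
            for k in range(1, n_replicates + 1):
                if total > 0 and depth > 0:
                    counts = (rs if base is None else stream(base, "experiment", "sequencing", t, int(d * 1000), k)).multinomial(
                        int(depth), row / total
                    )
                else:
                    counts = np.zeros(len(library), dtype=np.int64)
                day_columns[d][f"tumor{t + 1}_rep{k}"] = counts

    count_tables = {
        d: CountTable(pd.DataFrame(cols, index=library.barcode_ids), units="reads")
        for d, cols in day_columns.items()
    }
    truth = {
        "q": q,
        "n_tumors": n_tumors,
        "depth": int(depth),
        "n_replicates": int(n_replicates),
        "sample_days_hr": list(sample_days),
        "total_cells": library.total_cells,
        "n_barcodes": len(library),
        "founder_totals": founders.sum(axis=1).tolist(),
        "founder_barcodes": [int(len(ix)) for ix in founder_index],
        "sim_params": {
            "g": params.g, "k": params.k, "gamma": params.gamma, "D": params.D,
            "s0": params.s0, "sigma": params.sigma, "dt": params.dt,
            "horizon": params.horizon, "mode": params.mode,
            "extinction_threshold": params.extinction_threshold,
        },
    }
    return ExperimentBundle(
        library=library,
        founders=founders,
        trajectories=trajectories,
        founder_index=founder_index,
        count_tables=count_tables,
        truth=truth,
    )
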