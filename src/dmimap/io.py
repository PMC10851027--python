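"""Readers/writers for trajectory, envelope and scan tables.

All on-disk formats are plain tab-separated text. Trajectory tables carry
one frequency column per sampled generation (``freq_g<g>``, 6 decimal
places) plus a JSON sidecar with the seed. External allele-frequency data
can come from the same dialect or from PoPoolation2 "sync" files
(chrom, pos, ref, then one ``A:T:C:G:N:del`` count column per population).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .drift import DriftEnvelope
from .scan import DMIEstimate, ScanResult
from .simulate import Trajectory

__all__ = [
    "write_trajectory", "read_frequency_table", "load_population_frequencies",
    "write_envelope", "read_envelope",
    "write_scan", "write_estimates", "read_sync",
]

_SYNC_BASES = {"A": 0, "T": 1, "C": 2, "G": 3}


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"chromosome": traj.chromosome, "position": traj.position})
    for i, g in enumerate(traj.generations):
        df[f"freq_g{g}"] = traj.frequencies[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"seed": repr(traj.seed), "generations": list(traj.generations),
               "n_loci": int(len(traj.position))}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_frequency_table(path) -> pd.DataFrame:
    """Read a trajectory/frequency TSV; raises on empty or malformed input."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty frequency table")
    for col in ("chromosome", "position"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    freq_cols = [c for c in df.columns if c.startswith("freq")]
    if not freq_cols:
        raise ValueError(f"{path}: no frequency columns (freq*)")
    bad = ~df[freq_cols].map(np.isfinite).to_numpy() | \
        (df[freq_cols].to_numpy() < 0) | (df[freq_cols].to_numpy() > 1)
    if bad.any():
        raise ValueError(f"{path}: frequencies outside [0, 1]")
    return df


def load_population_frequencies(paths: Sequence, generation: int) -> tuple[np.ndarray, ...]:
    """Stack one generation's frequencies across per-population tables.

    Returns (freqs (n_pops, n_loci), chromosome, position). All populations
    must describe the identical loci, in order.
    """
    col = f"freq_g{generation}"
    chrom = pos = None
    rows = []
    for p in paths:
        df = read_frequency_table(p)
        if col not in df.columns:
            raise ValueError(f"{p}: generation {generation} not present")
        if chrom is None:
            chrom = df["chromosome"].to_numpy()
            pos = df["position"].to_numpy()
        elif not (np.array_equal(chrom, df["chromosome"].to_numpy())
                  and np.array_equal(pos, df["position"].to_numpy())):
            raise ValueError(f"{p}: loci differ from the first population's loci")
        rows.append(df[col].to_numpy())
    if not rows:
        raise ValueError("no population files given")
    return np.vstack(rows), chrom, pos


def write_envelope(env: DriftEnvelope, path) -> None:
    frames = []
    for i, g in enumerate(env.generations):
        frames.append(pd.DataFrame({
            "chromosome": env.chromosome, "position": env.position,
            "generation": g, "q025": env.lower[i], "q975": env.upper[i],
        }))
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_envelope(path, n_neutral_sims: int = 0, tail_prob: float = 0.05) -> DriftEnvelope:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty envelope table")
    gens = tuple(int(g) for g in sorted(df["generation"].unique()))
    first = df[df["generation"] == gens[0]]
    chrom = first["chromosome"].to_numpy()
    pos = first["position"].to_numpy()
    lower = np.empty((len(gens), len(pos)))
    upper = np.empty_like(lower)
    for i, g in enumerate(gens):
        sub = df[df["generation"] == g]
        if len(sub) != len(pos):
            raise ValueError(f"{path}: locus count differs across generations")
        lower[i] = sub["q025"].to_numpy()
        upper[i] = sub["q975"].to_numpy()
    return DriftEnvelope(chromosome=chrom, position=pos, generations=gens,
                         lower=lower, upper=upper,
                         n_neutral_sims=n_neutral_sims, tail_prob=tail_prob)


def write_scan(scan: ScanResult, path) -> None:
    pd.DataFrame({
        "chromosome": scan.chromosome, "position": scan.position,
        "k": scan.k, "p": scan.p, "q": scan.q,
        "significant": scan.significant.astype(int),
    }).to_csv(path, sep="\t", index=False)


def write_estimates(estimates: Sequence[DMIEstimate] | None, path) -> None:
    records = [] if estimates is None else [
        {"mode": e.mode, "chromosome": e.chromosome, "start": e.start,
         "end": e.end, "peak_position": e.peak_position,
         "peak_neglog10p": e.peak_neglog10p, "n_loci": e.n_loci}
        for e in estimates
    ]
    Path(path).write_text(json.dumps({"no_call": estimates is None,
                                      "estimates": records}, indent=1))


def read_sync(path, species1_allele: str = "ref") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse a PoPoolation2 sync file into species-1 allele frequencies.

    ``species1_allele`` is either ``"ref"`` (use each row's reference base)
    or a fixed base among A/T/C/G. Returns (freqs (n_pops, n_loci), chrom,
    pos); frequency is the designated allele's count over the four
    nucleotide counts. Malformed rows or ragged population columns raise
    ``ValueError``.
    """
    if species1_allele != "ref" and species1_allele not in _SYNC_BASES:
        raise ValueError("species1_allele must be 'ref' or one of A/T/C/G")
    chroms, positions, freq_rows = [], [], []
    n_pops = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: expected chrom, pos, ref and "
                                 f"counts, got {len(fields)} fields")
            chrom, pos, ref = fields[0], fields[1], fields[2].upper()
            pops = fields[3:]
            if n_pops is None:
                n_pops = len(pops)
            elif len(pops) != n_pops:
                raise ValueError(f"{path}:{ln}: inconsistent population count")
            allele = ref if species1_allele == "ref" else species1_allele
            if allele not in _SYNC_BASES:
                raise ValueError(f"{path}:{ln}: reference base {ref!r} is not A/T/C/G")
            row = []
            for col in pops:
                parts = col.split(":")
                if len(parts) != 6:
                    raise ValueError(f"{path}:{ln}: malformed count column {col!r}")
                try:
                    counts = [int(x) for x in parts]
                except ValueError:
                    raise ValueError(f"{path}:{ln}: non-integer count in {col!r}") from None
                total = sum(counts[:4])
                if total == 0:
                    raise ValueError(f"{path}:{ln}: zero coverage")
                row.append(counts[_SYNC_BASES[allele]] / total)
            chroms.append(chrom)
            try:
                positions.append(int(pos))
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer position {pos!r}") from None
            freq_rows.append(row)
    if not freq_rows:
        raise ValueError(f"{path}: no data rows")
    return (np.array(freq_rows).T, np.array(chroms), np.array(positions))
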