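"""Shared fixtures: small synthetic datasets and independent brute-force oracles.

The oracle helpers deliberately avoid the library's vectorized code paths —
they re-derive every quantity with plain per-read / per-codon Python loops so
the tests check the implementation against independent arithmetic.
"""

from __future__ import annotations

import numpy as np
import pytest

from ribodwell import (
    STANDARD_CODE,
    Annotation,
    default_scenario,
    filter_by_length,
)

OFFSET = 15


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def small_scenario():
    """20 genes at reduced depth: fast enough for per-read Python oracles."""
    return default_scenario(seed=7, n_genes=20, depth=5, rnaseq_depth=100_000)


@pytest.fixture(scope="session")
def small_filtered_rpf(small_scenario):
    return filter_by_length(small_scenario.rpf_reads)


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_profile(reads, annotation: Annotation, offset: int = OFFSET):
    """Per-read loop re-deriving A-site codon counts and the frame fraction."""
    counts = {t.id: np.zeros(t.n_codons, dtype=np.int64)
              for t in annotation if t.is_coding}
    lib = n_in = n_out = 0
    for r in reads:
        t = annotation[r.transcript_id]
        if t.biotype in ("rRNA", "tRNA"):
            continue
        lib += 1
        if not t.is_coding:
            continue
        pos = r.start + offset
        if not (t.cds_start <= pos < t.cds_end):
            continue
        rel = pos - t.cds_start
        if rel % 3 == 0:
            counts[t.id][rel // 3] += 1
            n_in += 1
        else:
            n_out += 1
    frac = n_in / (n_in + n_out) if n_in + n_out else float("nan")
    return counts, lib, frac


def brute_rpkm(reads, annotation: Annotation):
    """Per-read interval-intersection counting and closed-form RPKM."""
    counts = {t.id: 0 for t in annotation if t.is_coding}
    lib = 0
    for r in reads:
        t = annotation[r.transcript_id]
        if t.biotype in ("rRNA", "tRNA"):
            continue
        lib += 1
        if t.is_coding and r.start < t.cds_end and r.start + r.length > t.cds_start:
            counts[t.id] += 1
    rpkm = {tid: counts[tid] * 1e9 / (len(annotation[tid]) * lib) for tid in counts}
    return counts, lib, rpkm


def brute_cdt(profile_counts, lib_size, rpkm, annotation: Annotation,
              code=STANDARD_CODE, min_rpkm=1.0, min_reads=1, trim=20):
    """Flat per-gene, per-codon loop re-deriving CDT from first principles."""
    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    for tid, vec in profile_counts.items():
        g_rpkm = rpkm.get(tid, 0.0)
        if g_rpkm < min_rpkm or g_rpkm == 0:
            continue
        t = annotation[tid]
        codons = t.codons()
        n_sense = len(codons) - 1 if code.translate_codon(codons[-1]) == "*" else len(codons)
        for i in range(n_sense):
            c = codons[i]
            if code.table[c] == "*":
                continue
            if i < trim or i >= n_sense - trim:
                continue
            if vec[i] < min_reads:
                continue
            quotient = vec[i] * 1e6 / lib_size / g_rpkm
            sums[c] = sums.get(c, 0.0) + quotient
            ns[c] = ns.get(c, 0) + 1
    return {c: sums[c] / ns[c] for c in sums}, ns
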