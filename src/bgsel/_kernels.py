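"""Numba kernels for the forward simulation.

Population state is a pair of ragged CSR-like stores (deleterious and
neutral mutations kept separately): haplotype ``h`` owns the slice
``[starts[h], starts[h] + counts[h])`` of three parallel arrays —
``pos`` (global genomic coordinate, sorted ascending within each
haplotype), ``eff`` (signed heterozygous effect; 0.0 throughout the
neutral store) and ``born`` (origin generation).  Under the
infinite-sites model a continuous position uniquely identifies a
mutation, so kernels compare positions with exact float equality (they
are copied, never recomputed).

Transmission exploits the fixed crossover count: with a starting strand
and two crossover points per chromosome, the transmitted chromosome is
three contiguous segments, each copied wholesale from one parental
haplotype (a mutation present on both strands is transmitted from
whichever strand is active, which is equivalent to always transmitting
it).  New mutations, pre-sorted per gamete, are merged in during the
copy.
"""

import numpy as np
from numba import njit

__all__ = [
    "diploid_log_fitness",
    "diploid_log_fitness_constant",
    "make_offspring",
    "shared_by_all",
    "remove_positions",
]


@njit(cache=True)
def diploid_log_fitness(starts, counts, pos, eff, inv_h, out):
    """Log relative fitness of each diploid from the deleterious store.

    Multiplicative across sites, no epistasis: each heterozygous site
    contributes ``log(1 + sh)`` and each homozygous site
    ``log(1 + sh/h)`` (``inv_h = 1/h``).
    """
    n = out.shape[0]
    for d in range(n):
        a0 = starts[2 * d]
        na = counts[2 * d]
        b0 = starts[2 * d + 1]
        nb = counts[2 * d + 1]
        i = 0
        j = 0
        lw = 0.0
        while i < na and j < nb:
            pa = pos[a0 + i]
            pb = pos[b0 + j]
            if pa == pb:
                lw += np.log1p(eff[a0 + i] * inv_h)
                i += 1
                j += 1
            elif pa < pb:
                lw += np.log1p(eff[a0 + i])
                i += 1
            else:
                lw += np.log1p(eff[b0 + j])
                j += 1
        while i < na:
            lw += np.log1p(eff[a0 + i])
            i += 1
        while j < nb:
            lw += np.log1p(eff[b0 + j])
            j += 1
        out[d] = lw


@njit(cache=True)
def diploid_log_fitness_constant(starts, counts, pos, log_het, log_hom, out):
    """Log relative fitness when every deleterious effect is identical.

    Only the number of heterozygous and homozygous sites matters:
    ``logw = n_het * log(1+sh) + n_hom * log(1+sh/h)``.  The walk counts
    shared positions (homozygous sites) between the two haplotypes.
    """
    n = out.shape[0]
    for d in range(n):
        a0 = starts[2 * d]
        na = counts[2 * d]
        b0 = starts[2 * d + 1]
        nb = counts[2 * d + 1]
        i = 0
        j = 0
        m = 0
        while i < na and j < nb:
            pa = pos[a0 + i]
            pb = pos[b0 + j]
            if pa == pb:
                m += 1
                i += 1
                j += 1
            elif pa < pb:
                i += 1
            else:
                j += 1
        out[d] = (na + nb - 2 * m) * log_het + m * log_hom


@njit(cache=True)
def make_offspring(
    starts,
    counts,
    pos,
    eff,
    born,
    parents,
    xo_a,
    xo_b,
    xo_start,
    chrom_len,
    n_chrom,
    new_off,
    new_pos,
    new_eff,
    gen_now,
    out_starts,
    out_pos,
    out_eff,
    out_born,
    out_counts,
):
    """Build one gamete per row of ``parents`` for one mutation store.

    For gamete ``g`` from diploid parent ``p``: per chromosome ``c`` the
    active strand starts as ``xo_start[g, c]`` (0 = parent's first
    haplotype) and switches at the crossover coordinates
    ``xo_a[g, c] <= xo_b[g, c]`` (global; may exceed the chromosome end
    to encode fewer than two crossovers).  New mutations for gamete g
    (``new_pos[new_off[g]:new_off[g+1]]``, sorted) are merged in with
    origin generation ``gen_now``.  Output slices start at
    ``out_starts[g]`` (pre-sized upper bounds); actual lengths go to
    ``out_counts``.
    """
    n_gametes = parents.shape[0]
    for g in range(n_gametes):
        p = parents[g]
        a0 = starts[2 * p]
        na = counts[2 * p]
        b0 = starts[2 * p + 1]
        nb = counts[2 * p + 1]
        w = out_starts[g]
        k = new_off[g]
        kend = new_off[g + 1]
        ia = 0  # running pointer into haplotype A, monotone across segments
        ib = 0
        for c in range(n_chrom):
            x0 = c * chrom_len
            x1 = x0 + chrom_len
            s = xo_start[g, c]
            p1 = min(max(xo_a[g, c], x0), x1)
            p2 = min(max(xo_b[g, c], x0), x1)
            for seg in range(3):
                if seg == 0:
                    hi = p1
                    strand = s
                elif seg == 1:
                    hi = p2
                    strand = 1 - s
                else:
                    hi = x1
                    strand = s
                if strand == 0:
                    # copy from A up to hi, merging new mutations; skip B
                    while ia < na and pos[a0 + ia] < hi:
                        x = pos[a0 + ia]
                        while k < kend and new_pos[k] < x:
                            out_pos[w] = new_pos[k]
                            out_eff[w] = new_eff[k]
                            out_born[w] = gen_now
                            w += 1
                            k += 1
                        out_pos[w] = x
                        out_eff[w] = eff[a0 + ia]
                        out_born[w] = born[a0 + ia]
                        w += 1
                        ia += 1
                    while ib < nb and pos[b0 + ib] < hi:
                        ib += 1
                else:
                    while ib < nb and pos[b0 + ib] < hi:
                        x = pos[b0 + ib]
                        while k < kend and new_pos[k] < x:
                            out_pos[w] = new_pos[k]
                            out_eff[w] = new_eff[k]
                            out_born[w] = gen_now
                            w += 1
                            k += 1
                        out_pos[w] = x
                        out_eff[w] = eff[b0 + ib]
                        out_born[w] = born[b0 + ib]
                        w += 1
                        ib += 1
                    while ia < na and pos[a0 + ia] < hi:
                        ia += 1
                while k < kend and new_pos[k] < hi:
                    out_pos[w] = new_pos[k]
                    out_eff[w] = new_eff[k]
                    out_born[w] = gen_now
                    w += 1
                    k += 1
        # positions are drawn inside the genome, but flush defensively
        while k < kend:
            out_pos[w] = new_pos[k]
            out_eff[w] = new_eff[k]
            out_born[w] = gen_now
            w += 1
            k += 1
        out_counts[g] = w - out_starts[g]


@njit(cache=True)
def shared_by_all(starts, counts, pos):
    """Positions carried by every haplotype (candidates for fixation)."""
    n_hap = starts.shape[0]
    n0 = counts[0]
    s0 = starts[0]
    cand = pos[s0 : s0 + n0].copy()
    m = n0
    for h in range(1, n_hap):
        if m == 0:
            break
        a0 = starts[h]
        na = counts[h]
        i = 0
        j = 0
        w = 0
        while i < m and j < na:
            ci = cand[i]
            pj = pos[a0 + j]
            if ci == pj:
                cand[w] = ci
                w += 1
                i += 1
                j += 1
            elif ci < pj:
                i += 1
            else:
                j += 1
        m = w
    return cand[:m]


@njit(cache=True)
def remove_positions(starts, counts, pos, eff, born, rem):
    """Delete the sorted positions ``rem`` from every haplotype, in place."""
    n_hap = starts.shape[0]
    n_rem = rem.shape[0]
    for h in range(n_hap):
        a0 = starts[h]
        na = counts[h]
        w = a0
        j = 0
        for i in range(na):
            x = pos[a0 + i]
            while j < n_rem and rem[j] < x:
                j += 1
            if j < n_rem and rem[j] == x:
                continue
            pos[w] = x
            eff[w] = eff[a0 + i]
            born[w] = born[a0 + i]
            w += 1
        counts[h] = w - a0
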