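"""Numba kernels for single-locus Wright-Fisher simulation.

All kernels operate on allele *counts* (not individuals): a gene is a single
non-recombining biallelic locus, so the population state is fully described by
the LOF allele count (autosomes) or by female genotype counts plus the male
hemizygote count (non-PAR X).  Each generation applies, in order, selection on
parents, mutation in transmission, and binomial (multinomial on the X)
resampling at the next generation's size.

While the locus sits at a monomorphic boundary (count 0, or fixed) nothing but
mutation can move it, so the waiting time to the next polymorphic state is
geometric; the kernels jump over those waits exactly instead of sampling every
generation.  This is an exact acceleration of the per-generation chain.

Seeding: every kernel takes an integer seed and is deterministic given it.
"""

import numpy as np
from numba import njit

# fitness regimes: genotypes (wildtype hom, het, LOF hom) have fitness
# (1, 1-hs, 1-s); hemizygous males (1, 1-s).


@njit(cache=False)
def _sel_freq(q, h, s):
    """Post-selection allele frequency for HWE genotypes at frequency q."""
    if q <= 0.0 or q >= 1.0 or s == 0.0:
        return q
    hs = h * s
    waa = 1.0 - s
    wAa = 1.0 - hs
    num = q * q * waa + q * (1.0 - q) * wAa
    den = q * q * waa + 2.0 * q * (1.0 - q) * wAa + (1.0 - q) * (1.0 - q)
    return num / den


@njit(cache=False)
def _cond_binomial_ge1(n, p):
    """Draw from Binomial(n, p) conditioned on being >= 1 (inverse CDF walk)."""
    p0 = (1.0 - p) ** n
    target = np.random.random() * (1.0 - p0)
    pmf = p0
    cum = 0.0
    k = 0
    while k < n:
        # pmf(k+1) from pmf(k)
        pmf = pmf * (n - k) / (k + 1.0) * p / (1.0 - p)
        cum += pmf
        k += 1
        if cum >= target:
            return k
    return n


@njit(cache=False)
def _geometric(p):
    """Trials to first success; huge sentinel when p is (numerically) zero."""
    if p <= 0.0:
        return np.int64(1) << 62
    return np.int64(np.random.geometric(p))


@njit(cache=False)
def _wf_autosome_one(lengths, sizes, u, v, h, s, s_first, count0, n2_prev):
    """Run one locus through all epochs; returns (final_count, final_2N).

    ``lengths``/``sizes`` are oldest-first epoch lengths and diploid sizes
    (burn-in included as the first entry).  ``s_first`` is the selection
    coefficient applied during the first (burn-in) epoch — pass ``s`` for
    selection throughout or 0 for a neutral burn-in.  ``count0`` is the LOF
    count on entry at ``n2_prev`` chromosomes (pass 0, 2 * sizes[0] to start
    fresh).
    """
    count = count0
    n2p = n2_prev
    for e in range(lengths.shape[0]):
        s_eff = s_first if e == 0 else s
        n2 = 2 * sizes[e]
        # binomial resampling at the new size
        if n2 != n2p:
            if count == 0:
                pass
            elif count == n2p:
                count = n2
            else:
                count = np.random.binomial(n2, count / n2p)
        n2p = n2
        g = 0
        glen = lengths[e]
        while g < glen:
            if count == 0:
                # only forward mutation acts; jump to the next arrival
                p_leave = 1.0 - (1.0 - u) ** n2
                t = _geometric(p_leave)
                if t > glen - g:
                    g = glen
                else:
                    g += t
                    count = _cond_binomial_ge1(n2, u)
            elif count == n2:
                # only back mutation acts
                p_leave = 1.0 - (1.0 - v) ** n2
                t = _geometric(p_leave)
                if t > glen - g:
                    g = glen
                else:
                    g += t
                    count = n2 - _cond_binomial_ge1(n2, v)
            else:
                q = count / n2
                qs = _sel_freq(q, h, s_eff)
                p = qs * (1.0 - v) + (1.0 - qs) * u
                count = np.random.binomial(n2, p)
                g += 1
    return count, n2p


@njit(cache=False)
def _wf_autosome_batch(
    seed, lengths, sizes, u_arr, v_arr, h_arr, s_arr, n_chrom, burnin_with_selection
):
    """Independent replicates; returns (pop_freq, sample_count) per replicate."""
    np.random.seed(seed)
    reps = u_arr.shape[0]
    pop_freq = np.empty(reps, dtype=np.float64)
    sample_count = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        s_first = s_arr[r] if burnin_with_selection else 0.0
        count, n2 = _wf_autosome_one(
            lengths, sizes, u_arr[r], v_arr[r], h_arr[r], s_arr[r], s_first, 0, 2 * sizes[0]
        )
        q = count / n2
        pop_freq[r] = q
        if q <= 0.0:
            sample_count[r] = 0
        elif q >= 1.0:
            sample_count[r] = n_chrom
        else:
            sample_count[r] = np.random.binomial(n_chrom, q)
    return pop_freq, sample_count


@njit(cache=False)
def _wf_allele_age_batch(seed, lengths, sizes, mu, h, s, reps_target, max_attempts):
    """Age of an allele segregating at present (one mutation at a time).

    A single-copy mutation arises, only while the locus is monomorphic
    wildtype, with probability min(1, 2N mu) per generation; there is no
    recurrent or back mutation while the locus segregates.  Conditional on
    0 < count < 2N at present, the age is the number of generations since the
    locus was last invariant.  Fixation (count == 2N) is absorbing and the
    replicate is discarded.  Returns (ages, attempts_used); ages is truncated
    to the entries actually filled (caller checks attempts).
    """
    np.random.seed(seed)
    total = np.int64(0)
    for e in range(lengths.shape[0]):
        total += lengths[e]
    ages = np.empty(reps_target, dtype=np.int64)
    got = 0
    attempts = 0
    while got < reps_target and attempts < max_attempts:
        attempts += 1
        count = np.int64(0)
        last_inv = total  # generations before present when last invariant
        fixed = False
        elapsed = np.int64(0)
        for e in range(lengths.shape[0]):
            n2 = 2 * sizes[e]
            p_arr = min(1.0, n2 * mu)
            glen = lengths[e]
            g = 0
            while g < glen:
                if fixed:
                    elapsed += glen - g
                    g = glen
                    break
                if count == 0:
                    # wait for the next arrival within this epoch
                    t = _geometric(p_arr)
                    if t > glen - g:
                        elapsed += glen - g
                        g = glen
                        last_inv = total - elapsed
                    else:
                        g += t
                        elapsed += t
                        last_inv = total - elapsed + 1
                        count = 1
                else:
                    q = count / n2
                    qs = _sel_freq(q, h, s)
                    count = np.random.binomial(n2, qs)
                    g += 1
                    elapsed += 1
                    if count == n2:
                        fixed = True
                    elif count == 0:
                        last_inv = total - elapsed
            # size change at next epoch boundary
            if e + 1 < lengths.shape[0]:
                n2n = 2 * sizes[e + 1]
                if count > 0 and not fixed and n2n != n2:
                    count = np.random.binomial(n2n, count / n2)
                    if count == 0:
                        last_inv = total - elapsed
        if not fixed and count > 0:
            ages[got] = last_inv
            got += 1
    return ages[:got], attempts


# ---------------------------------------------------------------------------
# non-PAR X: two sexes, hemizygous males
# ---------------------------------------------------------------------------


@njit(cache=False)
def _x_gamete_freqs(naa, nAa, nf, na, nm, h, s):
    """Post-selection egg and sperm LOF frequencies from parental counts."""
    hs = h * s
    nAA = nf - naa - nAa
    wf = naa * (1.0 - s) + nAa * (1.0 - hs) + nAA
    if wf <= 0.0:
        qe = 0.0
    else:
        qe = (naa * (1.0 - s) + 0.5 * nAa * (1.0 - hs)) / wf
    nA = nm - na
    wm = na * (1.0 - s) + nA
    if wm <= 0.0:
        qs_ = 0.0
    else:
        qs_ = na * (1.0 - s) / wm
    return qe, qs_


@njit(cache=False)
def _wf_x_one(lengths, sizes, u_f, v_f, u_m, v_m, h, s, s_first, parental_mutation):
    """One non-PAR X locus through all epochs.

    Returns (q_female, q_male) at present.  State: ``naa``/``nAa`` female
    genotype counts among N/2 females, ``na`` LOF count among N/2 males.
    ``parental_mutation``: apply germline mutation to the parents before
    selection (the fertility-stage variant) instead of to transmitted gametes.
    """
    naa = np.int64(0)
    nAa = np.int64(0)
    na = np.int64(0)
    nf = sizes[0] // 2
    nm = sizes[0] - nf
    for e in range(lengths.shape[0]):
        s_eff = s_first if e == 0 else s
        nf_new = sizes[e] // 2
        nm_new = sizes[e] - nf_new
        # resample state at the new sex-specific sizes
        if nf_new != nf and naa + nAa > 0:
            paa = naa / nf
            pAa = nAa / nf
            naa = np.random.binomial(nf_new, paa)
            nAa = np.random.binomial(nf_new - naa, min(1.0, pAa / max(1e-300, 1.0 - paa)))
        if nm_new != nm and na > 0:
            na = np.random.binomial(nm_new, na / nm)
        nf = nf_new
        nm = nm_new
        glen = lengths[e]
        g = 0
        while g < glen:
            if naa == 0 and nAa == 0 and na == 0:
                # monomorphic wildtype: geometric jump to the next arrival.
                # transmissions per generation: nf eggs + nf sperm (daughters),
                # nm eggs (sons)
                p_none = ((1.0 - u_f) ** (nf + nm)) * ((1.0 - u_m) ** nf)
                t = _geometric(1.0 - p_none)
                if t > glen - g:
                    g = glen
                    continue
                g += t
                # place the (single) new mutant copy
                w_egg_d = nf * u_f
                w_egg_s = nm * u_f
                w_sperm_d = nf * u_m
                tot = w_egg_d + w_egg_s + w_sperm_d
                r = np.random.random() * tot
                if r < w_egg_d + w_sperm_d:
                    nAa = 1  # heterozygous daughter
                else:
                    na = 1  # hemizygous son
                continue
            if parental_mutation:
                # mutate parental alleles, then select (no gamete mutation)
                nAA = nf - naa - nAa
                m1 = np.random.binomial(2 * nAA, u_f) if nAA > 0 else 0
                if m1 > nAA:
                    m1 = nAA  # ignore double hits within one female
                m2 = np.random.binomial(nAa, u_f) if nAa > 0 else 0
                b1 = np.random.binomial(nAa, v_f) if nAa > 0 else 0
                b2 = np.random.binomial(2 * naa, v_f) if naa > 0 else 0
                if b2 > naa:
                    b2 = naa
                nAa = nAa + m1 - m2 - b1 + b2
                naa = naa + m2 - b2
                nAq = nm - na
                mm = np.random.binomial(nAq, u_m) if nAq > 0 else 0
                bm = np.random.binomial(na, v_m) if na > 0 else 0
                na = na + mm - bm
                qe, qs_ = _x_gamete_freqs(naa, nAa, nf, na, nm, h, s_eff)
            else:
                qe, qs_ = _x_gamete_freqs(naa, nAa, nf, na, nm, h, s_eff)
                qe = qe * (1.0 - v_f) + (1.0 - qe) * u_f
                qs_ = qs_ * (1.0 - v_m) + (1.0 - qs_) * u_m
            # daughters: egg x sperm; sons: egg only
            paa = qe * qs_
            pAa = qe * (1.0 - qs_) + (1.0 - qe) * qs_
            naa = np.random.binomial(nf, paa)
            rem = 1.0 - paa
            nAa = np.random.binomial(nf - naa, min(1.0, pAa / max(1e-300, rem)))
            na = np.random.binomial(nm, qe)
            g += 1
    qf = (2.0 * naa + nAa) / (2.0 * nf)
    qm = na / nm
    return qf, qm


@njit(cache=False)
def _wf_x_batch(
    seed, lengths, sizes, u_f, v_f, u_m, v_m, h_arr, s_arr,
    nf_chrom, nm_chrom, parental_mutation, burnin_with_selection,
):
    """Replicated X simulations; returns (qf, qm, sample_count)."""
    np.random.seed(seed)
    reps = h_arr.shape[0]
    qf = np.empty(reps, dtype=np.float64)
    qm = np.empty(reps, dtype=np.float64)
    sample_count = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        s_first = s_arr[r] if burnin_with_selection else 0.0
        a, b = _wf_x_one(
            lengths, sizes, u_f[r], v_f[r], u_m[r], v_m[r],
            h_arr[r], s_arr[r], s_first, parental_mutation,
        )
        qf[r] = a
        qm[r] = b
        c = np.random.binomial(nf_chrom, a) if 0.0 < a < 1.0 else (nf_chrom if a >= 1.0 else 0)
        c += np.random.binomial(nm_chrom, b) if 0.0 < b < 1.0 else (nm_chrom if b >= 1.0 else 0)
        sample_count[r] = c
    return qf, qm, sample_count
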