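"""Numba kernels for profile-HMM forward/Viterbi scoring.

Scores are computed in natural-log space on emission *ratios* (state
emission over background), so flank and insert emissions contribute zero
and the null model enters only through its length term, subtracted at the
end. See `hmm_backend` for the generative architecture.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf
_LN2 = float(np.log(2.0))


@njit(cache=True)
def score_batch(
    qenc,  # (nq, Lmax) int8, residue codes 0-19, 20 = ambiguous
    qlen,  # (nq,) int64
    lme,  # (M, 21) log match-emission ratios; column 20 is 0 (background)
    ltmm,
    ltmi,
    ltmd,  # (M-1,) log core transitions from match (exit-scaled)
    ltim,
    ltii,  # (M-1,) log transitions from insert
    ltdm,
    ltdd,  # (M-1,) log transitions from delete
    ltme,  # (M,) log match->exit
    eta_n,  # N-flank self-loop prob; < 0 means "match the null"
    eta_c,  # C-flank self-loop prob; < 0 means "match the null"
    eta_null,  # null extension prob; < 0 means L/(L+1) per query
    viterbi,  # bool: max instead of sum
):
    nq = qenc.shape[0]
    M = lme.shape[0]
    out = np.empty(nq, dtype=np.float64)
    lentry = -np.log(M)
    m_prev = np.empty(M, dtype=np.float64)
    i_prev = np.empty(M, dtype=np.float64)
    d_prev = np.empty(M, dtype=np.float64)
    m_cur = np.empty(M, dtype=np.float64)
    i_cur = np.empty(M, dtype=np.float64)
    d_cur = np.empty(M, dtype=np.float64)
    for q in range(nq):
        L = qlen[q]
        e0 = eta_null if eta_null >= 0.0 else L / (L + 1.0)
        e_n = eta_n if eta_n >= 0.0 else e0
        e_c = eta_c if eta_c >= 0.0 else e0
        ln_en = np.log(e_n) if e_n > 0.0 else NEG_INF
        ln_1mn = np.log1p(-e_n)
        ln_ec = np.log(e_c) if e_c > 0.0 else NEG_INF
        ln_1mc = np.log1p(-e_c)
        for k in range(M):
            m_prev[k] = NEG_INF
            i_prev[k] = NEG_INF
            d_prev[k] = NEG_INF
        n_state = 0.0  # log prob of being in N after 0 emissions
        c_state = NEG_INF
        for i in range(1, L + 1):
            x = qenc[q, i - 1]
            b_prev = n_state + ln_1mn
            for k in range(M):
                s = b_prev + lentry
                if k > 0:
                    a1 = m_prev[k - 1] + ltmm[k - 1]
                    a2 = i_prev[k - 1] + ltim[k - 1]
                    a3 = d_prev[k - 1] + ltdm[k - 1]
                    if viterbi:
                        s = max(max(s, a1), max(a2, a3))
                    else:
                        s = np.logaddexp(np.logaddexp(s, a1), np.logaddexp(a2, a3))
                m_cur[k] = s + lme[k, x]
                if k < M - 1:
                    a = m_prev[k] + ltmi[k]
                    b = i_prev[k] + ltii[k]
                    i_cur[k] = max(a, b) if viterbi else np.logaddexp(a, b)
                else:
                    i_cur[k] = NEG_INF
            d_cur[0] = NEG_INF
            for k in range(1, M):
                a = m_cur[k - 1] + ltmd[k - 1]
                b = d_cur[k - 1] + ltdd[k - 1]
                d_cur[k] = max(a, b) if viterbi else np.logaddexp(a, b)
            e_state = NEG_INF
            for k in range(M):
                t = m_cur[k] + ltme[k]
                e_state = max(e_state, t) if viterbi else np.logaddexp(e_state, t)
            if M > 1:
                # D_M -> E with probability 1 (alignment may end in deletions)
                t = d_cur[M - 1]
                e_state = max(e_state, t) if viterbi else np.logaddexp(e_state, t)
            cc = c_state + ln_ec
            c_state = max(cc, e_state) if viterbi else np.logaddexp(cc, e_state)
            n_state = n_state + ln_en
            for k in range(M):
                m_prev[k] = m_cur[k]
                i_prev[k] = i_cur[k]
                d_prev[k] = d_cur[k]
        total = c_state + ln_1mc
        ln_null = (L - 1) * np.log(e0) + np.log1p(-e0)
        out[q] = (total - ln_null) / _LN2
    return out
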