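"""Profile-HMM construction and bit-score computation.

Two interchangeable engines sit behind one contract:

* the **reference engine**, a self-contained local-alignment profile HMM
  with a forward bit score, used throughout the test suite and the default
  for synthetic work; and
* the **external engine**, which delegates model building and scoring to
  HMMER via :mod:`pyhmmer` (see :mod:`hmmens.external`) and is the fidelity
  path for real seed alignments.

Reference-engine architecture
-----------------------------
Match states ``M_1..M_M`` are the alignment columns whose gap fraction is
below a threshold (default 0.5). Match emissions use mean residue counts
with a background-weighted pseudocount, ``e(a) = (c_a + alpha*f(a)) /
(sum_b c_b + alpha)``; insert emissions equal the background. Core
transitions (M->M/I/D, I->M/I, D->M/D) are estimated from per-sequence
state paths with pseudocount 1 per allowed transition. Local alignment is
realized by uniform free entry ``B -> M_k`` (probability ``1/M``) and a
free-exit hazard ``M_k -> E`` of ``1/(M-k+1)`` (so the exit point is not
biased toward either end); learned transitions out of ``M_k`` are scaled
by the remaining mass. Unmodeled flanking residues are emitted by ``N``
and ``C`` states at background frequency with a self-loop probability
that, by default, equals the null model's extension probability.

The bit score is ``log2 P_forward(q | model) - log2 P_null(q)`` with the
null an i.i.d. background model of geometric length (extension probability
``L/(L+1)`` for a length-``L`` query unless configured). A model whose
match emissions equal the background and whose transitions reduce it to
the null therefore scores exactly 0 bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np

from . import _kernels
from .io_formats import AMINO_ACIDS, GAP_CHARS, Alignment, Sequence

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AMBIG = 20
N_RESIDUES = 20


class BackendError(RuntimeError):
    """Raised when a model cannot be built or scored."""


@dataclass
class BackendConfig:
    """Engine selection and reference-engine hyperparameters."""

    engine: str = "reference"  # or "external"
    match_gap_threshold: float = 0.5
    pseudocount: float = 1.0
    background: np.ndarray | None = None  # (20,), sums to 1; None = uniform
    flank_self_prob: float | None = None  # None: match the null's extension prob
    null_ext_prob: float | None = None  # None: L/(L+1) per query
    external_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.engine not in {"reference", "external"}:
            raise ValueError(f"unknown engine {self.engine!r}")
        if not (0 < self.match_gap_threshold < 1):
            raise ValueError("match_gap_threshold must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (N_RESIDUES,) or abs(bg.sum() - 1.0) > 1e-9:
                raise ValueError("background must be 20 frequencies summing to 1")
            self.background = bg

    def bg(self) -> np.ndarray:
        if self.background is None:
            return np.full(N_RESIDUES, 1.0 / N_RESIDUES)
        return self.background


@dataclass(frozen=True)
class ScoreRecord:
    query_id: str
    model_id: str
    family_id: str
    bit_score: float


@dataclass
class ReferenceHMM:
    """Parameters of a reference-engine profile HMM (probability space)."""

    match_emissions: np.ndarray  # (M, 20)
    background: np.ndarray  # (20,)
    t_mm: np.ndarray  # (M-1,)
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    n_self_prob: float | None = None
    c_self_prob: float | None = None
    null_ext_prob: float | None = None
    _log_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    def exit_hazard(self) -> np.ndarray:
        """Free-exit probability from each match state: 1/(M-k+1), 1-based k."""
        m = self.M
        return 1.0 / (m - np.arange(m))

    def log_arrays(self) -> tuple:
        if self._log_cache is None:
            with np.errstate(divide="ignore"):
                lme = np.empty((self.M, 21))
                lme[:, :N_RESIDUES] = np.log(self.match_emissions) - np.log(
                    self.background
                )[None, :]
                lme[:, _AMBIG] = 0.0
                ex = self.exit_hazard()
                keep = np.log1p(-ex[:-1]) if self.M > 1 else np.empty(0)
                ltme = np.log(ex)
                ltmm = np.log(self.t_mm) + keep
                ltmi = np.log(self.t_mi) + keep
                ltmd = np.log(self.t_md) + keep
                ltim = np.log(self.t_im)
                ltii = np.log(self.t_ii)
                ltdm = np.log(self.t_dm)
                ltdd = np.log(self.t_dd)
            object.__setattr__(
                self,
                "_log_cache",
                (lme, ltmm, ltmi, ltmd, ltim, ltii, ltdm, ltdd, ltme),
            )
        return self._log_cache

    def validate(self, atol: float = 1e-9) -> None:
        if self.M < 1:
            raise BackendError("model must have at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=atol):
            raise BackendError("match emissions do not sum to 1")
        if abs(self.background.sum() - 1.0) > atol:
            raise BackendError("background does not sum to 1")
        if self.M > 1:
            ex = self.exit_hazard()[:-1]
            m_out = ex + (1 - ex) * (self.t_mm + self.t_mi + self.t_md)
            if not np.allclose(m_out, 1.0, atol=atol):
                raise BackendError("match transition distributions do not sum to 1")
            if not np.allclose(self.t_im + self.t_ii, 1.0, atol=atol):
                raise BackendError("insert transition distributions do not sum to 1")
            if not np.allclose(self.t_dm + self.t_dd, 1.0, atol=atol):
                raise BackendError("delete transition distributions do not sum to 1")

    def to_json(self) -> str:
        payload = {
            "match_emissions": self.match_emissions.tolist(),
            "background": self.background.tolist(),
            "transitions": {
                name: getattr(self, f"t_{name}").tolist()
                for name in ("mm", "mi", "md", "im", "ii", "dm", "dd")
            },
            "n_self_prob": self.n_self_prob,
            "c_self_prob": self.c_self_prob,
            "null_ext_prob": self.null_ext_prob,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceHMM":
        d = json.loads(text)
        tr = d["transitions"]
        return cls(
            match_emissions=np.asarray(d["match_emissions"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            t_mm=np.asarray(tr["mm"], dtype=float),
            t_mi=np.asarray(tr["mi"], dtype=float),
            t_md=np.asarray(tr["md"], dtype=float),
            t_im=np.asarray(tr["im"], dtype=float),
            t_ii=np.asarray(tr["ii"], dtype=float),
            t_dm=np.asarray(tr["dm"], dtype=float),
            t_dd=np.asarray(tr["dd"], dtype=float),
            n_self_prob=d.get("n_self_prob"),
            c_self_prob=d.get("c_self_prob"),
            null_ext_prob=d.get("null_ext_prob"),
        )


@dataclass
class ProfileModel:
    """One profile HMM of an ensemble, with subset metadata.

    ``kind`` is ``"reference"`` (parameters in ``ref``) or ``"external"``
    (an opaque pyhmmer HMM in ``handle``).
    """

    model_id: str
    family_id: str
    subset_ids: frozenset[str]
    match_count: int
    kind: str = "reference"
    ref: ReferenceHMM | None = None
    handle: object | None = None
    size: int = 0
    mean_identity: float = 1.0


def match_columns(aln: Alignment, cfg: BackendConfig | None = None) -> np.ndarray:
    """Boolean mask of consensus (match) columns: gap fraction < threshold."""
    cfg = cfg or BackendConfig()
    mask = np.empty(aln.length, dtype=bool)
    n = aln.n_rows
    for c in range(aln.length):
        gaps = sum(1 for row in aln.rows if row.residues[c] in GAP_CHARS)
        mask[c] = gaps / n < cfg.match_gap_threshold
    if not mask.any():
        raise BackendError("no consensus columns in alignment")
    return mask


def _encode_residue(c: str) -> int:
    return _CODE.get(c, _AMBIG)


def encode_query(residues: str) -> np.ndarray:
    """Encode a query: uppercase, strip gaps, map ambiguity codes to 20."""
    clean = [c for c in residues.upper() if c not in GAP_CHARS]
    if not clean:
        raise ValueError("query has no residues after gap removal")
    return np.array([_encode_residue(c) for c in clean], dtype=np.int8)


def build_profile(
    aln: Alignment,
    cfg: BackendConfig | None = None,
    *,
    model_id: str = "model",
    family_id: str = "family",
    mean_identity: float = 1.0,
) -> ProfileModel:
    """Build a profile HMM from an alignment with the configured engine."""
    cfg = cfg or BackendConfig()
    if cfg.engine == "external":
        from .external import build_external_profile

        return build_external_profile(
            aln, cfg, model_id=model_id, family_id=family_id, mean_identity=mean_identity
        )
    mask = match_columns(aln, cfg)
    match_cols = np.flatnonzero(mask)
    M = len(match_cols)
    bg = cfg.bg()
    alpha = cfg.pseudocount

    counts = np.zeros((M, N_RESIDUES))
    for row in aln.rows:
        for k, c in enumerate(match_cols):
            ch = row.residues[c]
            if ch in GAP_CHARS:
                continue
            code = _CODE.get(ch)
            if code is not None:  # ambiguity codes contribute to no residue count
                counts[k, code] += 1.0
    emissions = (counts + alpha * bg[None, :]) / (
        counts.sum(axis=1, keepdims=True) + alpha
    )

    # transition counts from per-sequence state paths, pseudocount 1 each
    c_mm = np.ones(max(M - 1, 0))
    c_mi = np.ones(max(M - 1, 0))
    c_md = np.ones(max(M - 1, 0))
    c_im = np.ones(max(M - 1, 0))
    c_ii = np.ones(max(M - 1, 0))
    c_dm = np.ones(max(M - 1, 0))
    c_dd = np.ones(max(M - 1, 0))
    col_to_match = {int(c): k for k, c in enumerate(match_cols)}
    for row in aln.rows:
        path: list[tuple[str, int]] = []
        last_match = -1
        for c in range(aln.length):
            ch = row.residues[c]
            if c in col_to_match:
                k = col_to_match[c]
                path.append(("D" if ch in GAP_CHARS else "M", k))
                last_match = k
            elif ch not in GAP_CHARS:
                if 0 <= last_match <= M - 2:  # interior insert; ends are flank
                    path.append(("I", last_match))
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 == "M" and s2 == "M" and k2 == k1 + 1:
                c_mm[k1] += 1
            elif s1 == "M" and s2 == "I" and k2 == k1:
                c_mi[k1] += 1
            elif s1 == "M" and s2 == "D" and k2 == k1 + 1:
                c_md[k1] += 1
            elif s1 == "I" and s2 == "I" and k2 == k1:
                c_ii[k1] += 1
            elif s1 == "I" and s2 == "M" and k2 == k1 + 1:
                c_im[k1] += 1
            elif s1 == "D" and s2 == "D" and k2 == k1 + 1:
                c_dd[k1] += 1
            elif s1 == "D" and s2 == "M" and k2 == k1 + 1:
                c_dm[k1] += 1
            # D<->I and other adjacencies are outside the allowed set

    m_tot = c_mm + c_mi + c_md
    i_tot = c_im + c_ii
    d_tot = c_dm + c_dd
    ref = ReferenceHMM(
        match_emissions=emissions,
        background=bg,
        t_mm=c_mm / m_tot,
        t_mi=c_mi / m_tot,
        t_md=c_md / m_tot,
        t_im=c_im / i_tot,
        t_ii=c_ii / i_tot,
        t_dm=c_dm / d_tot,
        t_dd=c_dd / d_tot,
        n_self_prob=cfg.flank_self_prob,
        c_self_prob=cfg.flank_self_prob,
        null_ext_prob=cfg.null_ext_prob,
    )
    ref.validate()
    return ProfileModel(
        model_id=model_id,
        family_id=family_id,
        subset_ids=frozenset(aln.ids),
        match_count=M,
        kind="reference",
        ref=ref,
        size=aln.n_rows,
        mean_identity=mean_identity,
    )


def _score_encoded(
    ref: ReferenceHMM, qenc: np.ndarray, qlen: np.ndarray, viterbi: bool = False
) -> np.ndarray:
    lme, ltmm, ltmi, ltmd, ltim, ltii, ltdm, ltdd, ltme = ref.log_arrays()
    eta_n = -1.0 if ref.n_self_prob is None else float(ref.n_self_prob)
    eta_c = -1.0 if ref.c_self_prob is None else float(ref.c_self_prob)
    eta_null = -1.0 if ref.null_ext_prob is None else float(ref.null_ext_prob)
    return _kernels.score_batch(
        qenc,
        qlen,
        lme,
        ltmm,
        ltmi,
        ltmd,
        ltim,
        ltii,
        ltdm,
        ltdd,
        ltme,
        eta_n,
        eta_c,
        eta_null,
        viterbi,
    )


def pack_queries(queries: TypingSequence[Sequence]) -> tuple[np.ndarray, np.ndarray]:
    """Encode and pad queries into a batch for the scoring kernel."""
    encs = [encode_query(q.residues) for q in queries]
    lens = np.array([len(e) for e in encs], dtype=np.int64)
    qenc = np.zeros((len(encs), int(lens.max())), dtype=np.int8)
    for i, e in enumerate(encs):
        qenc[i, : len(e)] = e
    return qenc, lens


def forward_bitscore(model: ProfileModel, residues: str) -> float:
    """Forward log-odds bit score of a single query (reference engine)."""
    if model.kind != "reference" or model.ref is None:
        raise BackendError("forward_bitscore requires a reference-engine model")
    qenc = encode_query(residues)[None, :]
    qlen = np.array([qenc.shape[1]], dtype=np.int64)
    return float(_score_encoded(model.ref, qenc, qlen, viterbi=False)[0])


def viterbi_bitscore(model: ProfileModel, residues: str) -> float:
    """Best single-path bit score; never exceeds the forward score."""
    if model.kind != "reference" or model.ref is None:
        raise BackendError("viterbi_bitscore requires a reference-engine model")
    qenc = encode_query(residues)[None, :]
    qlen = np.array([qenc.shape[1]], dtype=np.int64)
    return float(_score_encoded(model.ref, qenc, qlen, viterbi=True)[0])


def score_sequences(
    model: ProfileModel,
    queries: TypingSequence[Sequence],
    cfg: BackendConfig | None = None,
) -> list[ScoreRecord]:
    """Best full-sequence bit score of each query against one model.

    Queries the engine reports no hit for are omitted (external engine
    only; the reference engine scores every query).
    """
    if not queries:
        return []
    if model.kind == "external":
        from .external import score_external

        return score_external(model, queries, cfg or BackendConfig(engine="external"))
    qenc, qlen = pack_queries(queries)
    scores = _score_encoded(model.ref, qenc, qlen, viterbi=False)
    return [
        ScoreRecord(q.id, model.model_id, model.family_id, float(s))
        for q, s in zip(queries, scores)
    ]


def sample_from_model(
    model: ProfileModel, rng: np.random.Generator
) -> str:
    """Sample a (flankless) sequence from the reference model's generative
    process: uniform entry, core walk with exit hazard."""
    ref = model.ref
    if ref is None:
        raise BackendError("sampling requires a reference-engine model")
    m = ref.M
    ex = ref.exit_hazard()
    out: list[int] = []
    k = int(rng.integers(m))
    state = "M"
    while True:
        if state == "M":
            out.append(int(rng.choice(N_RESIDUES, p=ref.match_emissions[k])))
            if rng.random() < ex[k]:
                break
            probs = np.array([ref.t_mm[k], ref.t_mi[k], ref.t_md[k]])
            choice = rng.choice(3, p=probs)
            if choice == 0:
                k, state = k + 1, "M"
            elif choice == 1:
                state = "I"
            else:
                k, state = k + 1, "D"
        elif state == "I":
            out.append(int(rng.choice(N_RESIDUES, p=ref.background)))
            if rng.random() < ref.t_im[k]:
                k, state = k + 1, "M"
        else:  # D
            if k == m - 1:
                break
            if rng.random() < ref.t_dm[k]:
                k, state = k + 1, "M"
            else:
                k, state = k + 1, "D"
    return "".join(AMINO_ACIDS[i] for i in out)
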