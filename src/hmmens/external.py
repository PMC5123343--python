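"""HMMER backend via pyhmmer.

Models are built with the standard ``hmmbuild``-equivalent builder in its
default mode and scored with the ``hmmsearch``-equivalent pipeline, keeping
the full-sequence bit score of each hit. The reporting threshold is set
very permissively (E = 1e6) so that weak hits remain observable for
inclusion-threshold sweeps; the acceleration filters stay at their
defaults unless overridden through ``BackendConfig.external_options``.
Queries with no reported hit are simply absent from the results (treated
as no-hit downstream).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence as TypingSequence

import pyhmmer
from pyhmmer.easel import Alphabet, DigitalSequenceBlock, TextMSA, TextSequence

from .hmm_backend import BackendConfig, BackendError, ProfileModel, ScoreRecord
from .io_formats import Alignment, Sequence

_DEFAULT_E = 1e6


def _alphabet() -> Alphabet:
    return Alphabet.amino()


def build_external_profile(
    aln: Alignment,
    cfg: BackendConfig,
    *,
    model_id: str = "model",
    family_id: str = "family",
    mean_identity: float = 1.0,
) -> ProfileModel:
    abc = _alphabet()
    try:
        msa = TextMSA(
            name=model_id.encode(),
            sequences=[
                TextSequence(name=row.id.encode(), sequence=row.residues)
                for row in aln.rows
            ],
        )
        builder = pyhmmer.plan7.Builder(abc)
        background = pyhmmer.plan7.Background(abc)
        hmm, _, _ = builder.build_msa(msa.digitize(abc), background)
    except Exception as exc:  # pragma: no cover - toolkit diagnostics vary
        raise BackendError(f"external build failed for {model_id!r}: {exc}") from exc
    return ProfileModel(
        model_id=model_id,
        family_id=family_id,
        subset_ids=frozenset(aln.ids),
        match_count=hmm.M,
        kind="external",
        handle=hmm,
        size=aln.n_rows,
        mean_identity=mean_identity,
    )


def score_external(
    model: ProfileModel,
    queries: TypingSequence[Sequence],
    cfg: BackendConfig | None = None,
) -> list[ScoreRecord]:
    if model.handle is None:
        raise BackendError(f"model {model.model_id!r} has no external handle")
    cfg = cfg or BackendConfig(engine="external")
    abc = _alphabet()
    options = {"E": _DEFAULT_E}
    options.update(cfg.external_options)
    background = pyhmmer.plan7.Background(abc)
    pipeline = pyhmmer.plan7.Pipeline(abc, background=background, **options)
    block = DigitalSequenceBlock(
        abc,
        [
            TextSequence(name=q.id.encode(), sequence=q.ungapped).digitize(abc)
            for q in queries
        ],
    )
    try:
        hits = pipeline.search_hmm(model.handle, block)
    except Exception as exc:  # pragma: no cover
        raise BackendError(f"external search failed for {model.model_id!r}: {exc}") from exc
    return [
        ScoreRecord(
            hit.name.decode() if isinstance(hit.name, bytes) else str(hit.name),
            model.model_id,
            model.family_id,
            float(hit.score),
        )
        for hit in hits
    ]


def save_external_model(model: ProfileModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        model.handle.write(fh, binary=False)


def load_external_model(path: str | Path):
    with pyhmmer.plan7.HMMFile(str(path)) as hf:
        return hf.read()
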