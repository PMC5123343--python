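"""Preprocessing: build and persist the ensemble-of-HMMs database.

For every family: accept or estimate a guide tree, recursively decompose
it, build one profile HMM per subset node (the root model always covers
the full seed alignment), and collect the per-family ensembles into a
database keyed by family id. Single-model mode — the degenerate
parameterization X=100%, Y=0% under which the root is never split — makes
the classifier equivalent to scoring one profile per family (the plain
HMMER-style baseline) without separate code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decomposition import (
    DecompositionParams,
    DecompositionTree,
    SubsetNode,
    decompose,
    estimate_guide_tree,
)
from .hmm_backend import BackendConfig, BackendError, ProfileModel, build_profile
from .io_formats import FamilyDatabase, FamilyRecord, induced_alignment

logger = logging.getLogger(__name__)

SINGLE_MODEL = dict(max_size_pct=100.0, min_identity_pct=0.0)


class EnsembleBuildError(RuntimeError):
    pass


@dataclass
class Ensemble:
    """The set of nested profile HMMs representing one family."""

    family_id: str
    models: list[ProfileModel]
    decomposition: DecompositionTree
    params: DecompositionParams
    threshold: float = 0.0

    @property
    def p(self) -> int:
        return len(self.models)

    @property
    def root_model(self) -> ProfileModel:
        return self.models[0]

    def validate(self) -> None:
        if self.p != self.decomposition.node_count:
            raise EnsembleBuildError("model count != decomposition node count")
        root_ids = self.root_model.subset_ids
        for model in self.models[1:]:
            if not model.subset_ids < root_ids:
                raise EnsembleBuildError(
                    "non-root model subset is not strictly nested in the root"
                )


@dataclass
class EnsembleDatabase:
    """Ensembles for every family, plus the build configuration."""

    ensembles: dict[str, Ensemble]
    fingerprint: str
    config: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.ensembles)

    @property
    def n_models(self) -> int:
        return sum(e.p for e in self.ensembles.values())

    def thresholds(self) -> dict[str, float]:
        return {fid: e.threshold for fid, e in self.ensembles.items()}

    def family_meta(self) -> dict[str, dict]:
        """Per-family seed size and root mean identity (for subgrouping)."""
        return {
            fid: {
                "size": e.root_model.size,
                "mean_identity": e.decomposition.root.mean_identity,
            }
            for fid, e in self.ensembles.items()
        }

    def iter_models(self):
        for ensemble in self.ensembles.values():
            yield from ensemble.models


def _family_rng(seed: int, family_id: str) -> np.random.Generator:
    h = int.from_bytes(
        hashlib.sha256(family_id.encode()).digest()[:4], "big"
    ) % (2**31)
    return np.random.default_rng([int(seed) % (2**31), h])


def config_fingerprint(params: DecompositionParams, cfg: BackendConfig) -> str:
    payload = {
        "max_size_pct": params.max_size_pct,
        "min_identity_pct": params.min_identity_pct,
        "hard_floor": params.hard_floor,
        "engine": cfg.engine,
        "match_gap_threshold": cfg.match_gap_threshold,
        "pseudocount": cfg.pseudocount,
        "background": None if cfg.background is None else list(cfg.background),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def build_ensemble(
    fam: FamilyRecord,
    params: DecompositionParams | None = None,
    cfg: BackendConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Ensemble:
    """Decompose one family and build a profile per subset node."""
    params = params or DecompositionParams()
    cfg = cfg or BackendConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    try:
        if fam.seed.n_rows == 1:
            root = SubsetNode(frozenset(fam.seed.ids), mean_identity=1.0, depth=0)
            dec = DecompositionTree(root)
        else:
            tree = estimate_guide_tree(fam.seed, fam.guide_tree_path)
            dec = decompose(fam.seed, tree, params, rng)
        models = []
        for idx, node in enumerate(dec.nodes()):
            sub_aln = (
                fam.seed
                if node.taxon_ids == frozenset(fam.seed.ids)
                else induced_alignment(fam.seed, node.taxon_ids)
            )
            models.append(
                build_profile(
                    sub_aln,
                    cfg,
                    model_id=f"{fam.family_id}.m{idx:03d}",
                    family_id=fam.family_id,
                    mean_identity=node.mean_identity,
                )
            )
    except (ValueError, BackendError) as exc:
        raise EnsembleBuildError(f"family {fam.family_id!r}: {exc}") from exc
    ensemble = Ensemble(
        family_id=fam.family_id,
        models=models,
        decomposition=dec,
        params=dataclasses.replace(params, n=fam.seed.n_rows),
        threshold=fam.threshold,
    )
    ensemble.validate()
    return ensemble


def build_database(
    db: FamilyDatabase,
    params: DecompositionParams | None = None,
    cfg: BackendConfig | None = None,
    seed: int = 0,
    single_hmm: bool = False,
    skip_errors: bool = False,
) -> EnsembleDatabase:
    """Build ensembles for every family with independent per-family rngs."""
    params = params or DecompositionParams()
    if single_hmm:
        params = dataclasses.replace(params, **SINGLE_MODEL)
    cfg = cfg or BackendConfig()
    ensembles: dict[str, Ensemble] = {}
    failures: dict[str, str] = {}
    for fam in db:
        try:
            ensembles[fam.family_id] = build_ensemble(
                fam, params, cfg, _family_rng(seed, fam.family_id)
            )
        except EnsembleBuildError as exc:
            if not skip_errors:
                raise
            failures[fam.family_id] = str(exc)
            logger.warning("skipping family %s: %s", fam.family_id, exc)
    if not ensembles:
        raise EnsembleBuildError("no family could be built")
    logger.info(
        "built %d ensembles, %d models total",
        len(ensembles),
        sum(e.p for e in ensembles.values()),
    )
    return EnsembleDatabase(
        ensembles=ensembles,
        fingerprint=config_fingerprint(params, cfg),
        config={
            "max_size_pct": params.max_size_pct,
            "min_identity_pct": params.min_identity_pct,
            "hard_floor": params.hard_floor,
            "engine": cfg.engine,
            "seed": int(seed),
            "single_hmm": bool(single_hmm),
            "skipped": failures,
        },
    )


def root_only_view(edb: EnsembleDatabase) -> EnsembleDatabase:
    """A view keeping only each family's root (full-seed) profile."""
    trimmed = {}
    for fid, ens in edb.ensembles.items():
        root = SubsetNode(
            ens.decomposition.root.taxon_ids,
            ens.decomposition.root.mean_identity,
            0,
        )
        trimmed[fid] = Ensemble(
            family_id=fid,
            models=[ens.root_model],
            decomposition=DecompositionTree(root),
            params=ens.params,
            threshold=ens.threshold,
        )
    return EnsembleDatabase(
        ensembles=trimmed, fingerprint=edb.fingerprint, config=dict(edb.config)
    )


# ---------------------------------------------------------------------------
# Persistence: one directory per family (decomposition JSON + model files)
# ---------------------------------------------------------------------------


def save_database(edb: EnsembleDatabase, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "config.json").write_text(
        json.dumps({"fingerprint": edb.fingerprint, "config": edb.config}, indent=1)
    )
    for fid, ens in edb.ensembles.items():
        fam_dir = path / "families" / fid
        fam_dir.mkdir(parents=True, exist_ok=True)
        (fam_dir / "decomposition.json").write_text(ens.decomposition.to_json())
        meta = {
            "family_id": fid,
            "threshold": ens.threshold,
            "params": {
                "max_size_pct": ens.params.max_size_pct,
                "min_identity_pct": ens.params.min_identity_pct,
                "hard_floor": ens.params.hard_floor,
                "n": ens.params.n,
            },
            "models": [
                {
                    "model_id": m.model_id,
                    "kind": m.kind,
                    "match_count": m.match_count,
                    "size": m.size,
                    "mean_identity": m.mean_identity,
                    "subset_ids": sorted(m.subset_ids),
                    "file": f"model_{i:03d}." + ("json" if m.kind == "reference" else "hmm"),
                }
                for i, m in enumerate(ens.models)
            ],
        }
        (fam_dir / "meta.json").write_text(json.dumps(meta, indent=1))
        for i, model in enumerate(ens.models):
            model_path = fam_dir / meta["models"][i]["file"]
            if model.kind == "reference":
                model_path.write_text(model.ref.to_json())
            else:
                from .external import save_external_model

                save_external_model(model, model_path)
    return path


def load_database(
    path: str | Path, expected_fingerprint: str | None = None
) -> EnsembleDatabase:
    from .hmm_backend import ReferenceHMM

    path = Path(path)
    config_path = path / "config.json"
    if not config_path.exists():
        raise FileNotFoundError(f"no ensemble database at {path}")
    top = json.loads(config_path.read_text())
    if expected_fingerprint and top["fingerprint"] != expected_fingerprint:
        warnings.warn(
            f"ensemble database fingerprint {top['fingerprint']} does not match "
            f"expected {expected_fingerprint}",
            stacklevel=2,
        )
    ensembles: dict[str, Ensemble] = {}
    for fam_dir in sorted((path / "families").iterdir()):
        if not fam_dir.is_dir():
            continue
        meta = json.loads((fam_dir / "meta.json").read_text())
        fid = meta["family_id"]
        dec = _decomposition_from_json((fam_dir / "decomposition.json").read_text())
        models = []
        for entry in meta["models"]:
            model_path = fam_dir / entry["file"]
            if not model_path.exists():
                raise FileNotFoundError(
                    f"missing model file {entry['file']} for model "
                    f"{entry['model_id']!r} in family {fid!r}"
                )
            if entry["kind"] == "reference":
                ref = ReferenceHMM.from_json(model_path.read_text())
                handle = None
            else:
                from .external import load_external_model

                ref = None
                handle = load_external_model(model_path)
            models.append(
                ProfileModel(
                    model_id=entry["model_id"],
                    family_id=fid,
                    subset_ids=frozenset(entry["subset_ids"]),
                    match_count=entry["match_count"],
                    kind=entry["kind"],
                    ref=ref,
                    handle=handle,
                    size=entry["size"],
                    mean_identity=entry["mean_identity"],
                )
            )
        p = meta["params"]
        ensembles[fid] = Ensemble(
            family_id=fid,
            models=models,
            decomposition=dec,
            params=DecompositionParams(
                max_size_pct=p["max_size_pct"],
                min_identity_pct=p["min_identity_pct"],
                hard_floor=p["hard_floor"],
                n=p["n"],
            ),
            threshold=meta["threshold"],
        )
    return EnsembleDatabase(
        ensembles=ensembles,
        fingerprint=top["fingerprint"],
        config=top.get("config", {}),
    )


def _decomposition_from_json(text: str) -> DecompositionTree:
    records = json.loads(text)
    nodes = [
        SubsetNode(frozenset(r["taxon_ids"]), r["mean_identity"], r["depth"])
        for r in records
    ]
    kids: dict[int, list[int]] = {}
    for r in records:
        if r["parent"] is not None:
            kids.setdefault(r["parent"], []).append(r["node"])
    for parent, children in kids.items():
        nodes[parent].children = (nodes[children[0]], nodes[children[1]])
    return DecompositionTree(nodes[0])
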