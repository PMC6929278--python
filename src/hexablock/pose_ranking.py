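"""Pose-level feature assembly, SVR scoring and decoy re-ranking.

Each docking pose is summarised by a fixed-layout vector built from ordered
*energy terms*.  A term contributes one feature group; the two groups native
to this package are

* group 6 — pooled MLAB (sequential-window) features of the pose's
  interface residues, and
* group 7 — pooled hexagon (spatial-window) features of the pose's
  interface residues,

with per-residue vectors pooled by the element-wise mean over interface
residues of both units (an empty interface pools to the zero vector and is
flagged).  Further energy terms (statistical contact potentials, secondary
structure terms, ...) plug in through the same :class:`EnergyTerm`
contract; a simplified amino-acid contact-propensity term ships as a
reference plug-in.

A support vector regression model is trained with interface RMSD as the
response, so low predicted values play the role of low energies: poses are
ranked by ascending prediction and the top-k reported.  A consensus over
the interfaces of the selected poses yields per-unit binding-residue
predictions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .local_features import (
    BlockScheme,
    DEFAULT_HEXAGON_SCHEME,
    DEFAULT_SEQUENTIAL_SCHEME,
    hexagon_features,
    hexagon_window,
    mlab_features,
    sequential_window,
)
from .residue_profiles import AA_INDEX, NormalizedPSSM, normalize_physchem
from .structure_model import (
    ContactSet,
    ResidueKey,
    Structure,
    contact_pairs,
    interface_residues,
)

__all__ = [
    "EnergyTerm",
    "TermError",
    "FeatureContext",
    "FeatureGroupVector",
    "PooledVector",
    "TrainingSet",
    "SvrConfig",
    "SvrModel",
    "RankedPoses",
    "pool_interface_features",
    "mlab_term",
    "hexagon_term",
    "contact_propensity_term",
    "propensity_term",
    "default_contact_propensity",
    "assemble_features",
    "assemble_many",
    "train_svr",
    "rank_and_select",
    "consensus_binding_residues",
    "save_model",
    "load_model",
    "run_group_ablation",
]

logger = logging.getLogger(__name__)


class TermError(RuntimeError):
    """An energy term failed on a pose."""


@dataclass
class FeatureContext:
    """Per-complex inputs shared by all poses: profiles, schemes, cutoffs.

    MLAB per-residue vectors depend only on the sequence position, so they
    are computed once per complex and reused for every pose.
    """

    profiles: Mapping[str, NormalizedPSSM]
    sequential_scheme: BlockScheme = DEFAULT_SEQUENTIAL_SCHEME
    hexagon_scheme: BlockScheme = DEFAULT_HEXAGON_SCHEME
    contact_cutoff: float = 6.0
    hexagon_cutoff: float = 10.0
    min_seq_sep: int = 4
    cross_chain: bool = True
    pooling: str = "mean"  # mean | sum | max
    _mlab_cache: Dict[ResidueKey, np.ndarray] = field(default_factory=dict, repr=False)

    def mlab_vectors(self, structure: Structure) -> Dict[ResidueKey, np.ndarray]:
        if not self._mlab_cache:
            for res in structure.all_residues():
                profile = self.profiles[res.chain_id]
                window = sequential_window(profile, res.seq_index)
                self._mlab_cache[res.key] = mlab_features(
                    window, self.sequential_scheme
                ).values
        return self._mlab_cache

    def hexagon_vectors(
        self, structure: Structure, keys: Sequence[ResidueKey]
    ) -> Dict[ResidueKey, np.ndarray]:
        out: Dict[ResidueKey, np.ndarray] = {}
        for key in keys:
            res = structure.residue(key)
            window = hexagon_window(
                structure, self.profiles, res,
                cutoff=self.hexagon_cutoff,
                min_seq_sep=self.min_seq_sep,
                cross_chain=self.cross_chain,
            )
            out[key] = hexagon_features(window, self.hexagon_scheme).values
        return out


@dataclass(frozen=True)
class EnergyTerm:
    """One feature group: a named, group-tagged pose -> vector contract."""

    name: str
    group_id: int
    compute: Callable[[Structure, FeatureContext, ContactSet], np.ndarray]

    def __post_init__(self):
        if not 1 <= self.group_id <= 7:
            raise ValueError("group_id must be in 1..7")


@dataclass(frozen=True)
class PooledVector:
    values: np.ndarray
    empty: bool


@dataclass(frozen=True)
class FeatureGroupVector:
    """Concatenated group sub-vectors for one pose, with layout metadata."""

    pose_id: str
    values: np.ndarray
    layout: Tuple[Tuple[str, int, int, int], ...]  # (name, group_id, offset, length)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"pose {self.pose_id}: non-finite feature values")


@dataclass
class TrainingSet:
    rows: List[FeatureGroupVector]
    responses: np.ndarray
    complex_ids: Optional[List[str]] = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.rows) != len(self.responses):
            raise ValueError("one response per feature row required")
        if np.any(self.responses < 0):
            raise ValueError("responses (interface RMSD) must be >= 0")

    def matrix(self) -> np.ndarray:
        return np.array([r.values for r in self.rows])


@dataclass(frozen=True)
class SvrConfig:
    """SVR hyperparameters; defaults are the conventional RBF settings.

    ``gamma=None`` means 1 / feature dimension.
    """

    kernel: str = "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: Optional[float] = None
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0 or self.epsilon <= 0:
            raise ValueError("C and epsilon must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class SvrModel:
    pipeline: Pipeline
    layout: Tuple[Tuple[str, int, int, int], ...]
    config: SvrConfig
    scheme_fingerprints: Tuple[str, str]  # (sequential, hexagon)
    alphabet_fingerprint: str = "".join(sorted(AA_INDEX))

    def predict(self, rows: Sequence[FeatureGroupVector]) -> np.ndarray:
        _check_layout(self.layout, rows)
        return self.pipeline.predict(np.array([r.values for r in rows]))


@dataclass
class RankedPoses:
    pose_ids: List[str]          # ascending predicted response
    predictions: np.ndarray
    selected: List[str]          # top-k subset

    def __post_init__(self):
        if np.any(np.diff(self.predictions) < 0):
            raise ValueError("predictions must be non-decreasing in rank order")


# ---------------------------------------------------------------------------
# per-pose feature terms
# ---------------------------------------------------------------------------

def pool_interface_features(
    pose: Structure,
    per_residue: Mapping[ResidueKey, np.ndarray],
    cutoff: float = 6.0,
    pooling: str = "mean",
    contacts: Optional[ContactSet] = None,
) -> PooledVector:
    """Pool per-residue vectors over the pose's interface residues.

    Both units' interface residues contribute; the default pooling is the
    element-wise mean (``sum`` and ``max`` are alternatives).  A pose with
    no contacts pools to the zero vector with the ``empty`` flag set.
    """
    if contacts is None:
        contacts = contact_pairs(pose, cutoff=cutoff)
    rec, lig = interface_residues(contacts)
    keys = sorted(rec | lig)
    dim = len(next(iter(per_residue.values())))
    if not keys:
        return PooledVector(values=np.zeros(dim), empty=True)
    stack = np.array([per_residue[k] for k in keys])
    if pooling == "mean":
        pooled = stack.mean(axis=0)
    elif pooling == "sum":
        pooled = stack.sum(axis=0)
    elif pooling == "max":
        pooled = stack.max(axis=0)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return PooledVector(values=pooled, empty=False)


def mlab_term(group_id: int = 6) -> EnergyTerm:
    """Group-6 term: pooled sequential MLAB features of interface residues."""

    def compute(pose: Structure, ctx: FeatureContext, contacts: ContactSet) -> np.ndarray:
        vectors = ctx.mlab_vectors(pose)
        return pool_interface_features(
            pose, vectors, cutoff=ctx.contact_cutoff,
            pooling=ctx.pooling, contacts=contacts,
        ).values

    return EnergyTerm(name="mlab", group_id=group_id, compute=compute)


def hexagon_term(group_id: int = 7) -> EnergyTerm:
    """Group-7 term: pooled hexagon spatial features of interface residues."""

    def compute(pose: Structure, ctx: FeatureContext, contacts: ContactSet) -> np.ndarray:
        rec, lig = interface_residues(contacts)
        keys = sorted(rec | lig)
        if not keys:
            ncols = next(iter(ctx.profiles.values())).scores.shape[1]
            return np.zeros(6 * ncols)
        vectors = ctx.hexagon_vectors(pose, keys)
        return pool_interface_features(
            pose, vectors, cutoff=ctx.contact_cutoff,
            pooling=ctx.pooling, contacts=contacts,
        ).values

    return EnergyTerm(name="hexagon", group_id=group_id, compute=compute)


def default_contact_propensity() -> np.ndarray:
    """Synthetic 20x20 contact-propensity table for the reference term.

    Built from the product of z-scored hydrophobicities (hydrophobic-
    hydrophobic contacts score favourably, i.e. negative).  This is a
    simplified stand-in for a statistics-derived contact potential and is
    intended for testing the plug-in contract, not for production scoring.
    """
    h = normalize_physchem().values[:, 0]
    return -np.outer(h, h)


def contact_propensity_term(pose: Structure, propensity: np.ndarray,
                            cutoff: float = 6.0,
                            contacts: Optional[ContactSet] = None) -> np.ndarray:
    """Simplified amino-acid contact-propensity energy: a 2-vector of
    (sum of pairwise propensities over interface contacts, contact count)."""
    propensity = np.asarray(propensity, dtype=float)
    if propensity.shape != (20, 20) or not np.all(np.isfinite(propensity)):
        raise ValueError("propensity must be a finite 20x20 table")
    if contacts is None:
        contacts = contact_pairs(pose, cutoff=cutoff)
    total = 0.0
    for (rkey, lkey) in contacts.pairs:
        r = pose.residue(rkey)
        l = pose.residue(lkey)
        total += propensity[AA_INDEX[r.one_letter], AA_INDEX[l.one_letter]]
    return np.array([total, float(len(contacts))])


def propensity_term(propensity: Optional[np.ndarray] = None, group_id: int = 1) -> EnergyTerm:
    """Wrap :func:`contact_propensity_term` as a pluggable group-1 term."""
    table = default_contact_propensity() if propensity is None else propensity

    def compute(pose: Structure, ctx: FeatureContext, contacts: ContactSet) -> np.ndarray:
        return contact_propensity_term(
            pose, table, cutoff=ctx.contact_cutoff, contacts=contacts
        )

    return EnergyTerm(name="contact_propensity", group_id=group_id, compute=compute)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_features(
    pose: Structure,
    terms: Sequence[EnergyTerm],
    ctx: FeatureContext,
    pose_id: str = "pose",
) -> FeatureGroupVector:
    """Concatenate the terms' sub-vectors in declared order, recording the
    layout.  A failing term raises :class:`TermError` naming the term."""
    if not terms:
        raise ValueError("at least one energy term is required")
    contacts = contact_pairs(pose, cutoff=ctx.contact_cutoff)
    parts: List[np.ndarray] = []
    layout: List[Tuple[str, int, int, int]] = []
    offset = 0
    for term in terms:
        try:
            sub = np.asarray(term.compute(pose, ctx, contacts), dtype=float).ravel()
        except Exception as exc:  # noqa: BLE001 - plug-in boundary
            raise TermError(f"term {term.name!r} failed on pose {pose_id}: {exc}") from exc
        layout.append((term.name, term.group_id, offset, sub.size))
        parts.append(sub)
        offset += sub.size
    return FeatureGroupVector(
        pose_id=pose_id, values=np.concatenate(parts), layout=tuple(layout)
    )


def assemble_many(
    poses: Sequence[Tuple[str, Structure]],
    terms: Sequence[EnergyTerm],
    ctx: FeatureContext,
) -> List[FeatureGroupVector]:
    """Assemble features for many poses; failing poses are logged and excluded."""
    rows: List[FeatureGroupVector] = []
    for pose_id, pose in poses:
        try:
            rows.append(assemble_features(pose, terms, ctx, pose_id=pose_id))
        except TermError as exc:
            logger.warning("excluding pose %s: %s", pose_id, exc)
    return rows


# ---------------------------------------------------------------------------
# SVR training and ranking
# ---------------------------------------------------------------------------

def _check_layout(expected, rows: Sequence[FeatureGroupVector]) -> None:
    for row in rows:
        if row.layout != tuple(expected):
            got = {(g[0], g[2], g[3]) for g in row.layout}
            want = {(g[0], g[2], g[3]) for g in expected}
            bad = sorted(g[0] for g in (want ^ got)) or ["<order>"]
            raise ValueError(
                f"pose {row.pose_id}: feature layout mismatch in group(s) {bad}"
            )


def train_svr(data: TrainingSet, config: SvrConfig = SvrConfig()) -> SvrModel:
    """Fit an SVR with interface-RMSD responses on the assembled features.

    Features are standardised to zero mean / unit variance with training
    statistics (unless disabled); refitting on identical input reproduces
    identical predictions.
    """
    if len(data.rows) < 2:
        raise ValueError("need at least 2 training poses")
    if np.unique(data.responses).size < 2:
        raise ValueError("responses are constant; nothing to regress")
    X = data.matrix()
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite values")
    gamma = config.gamma if config.gamma is not None else 1.0 / X.shape[1]
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        ("svr", SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon, gamma=gamma))
    )
    pipeline = Pipeline(steps)
    pipeline.fit(X, data.responses)
    return SvrModel(
        pipeline=pipeline,
        layout=data.rows[0].layout,
        config=config,
        scheme_fingerprints=(
            DEFAULT_SEQUENTIAL_SCHEME.fingerprint(),
            DEFAULT_HEXAGON_SCHEME.fingerprint(),
        ),
    )


def rank_and_select(
    model: SvrModel, poses: Sequence[FeatureGroupVector], k: int = 10
) -> RankedPoses:
    """Order poses by ascending predicted response (predicted interface RMSD
    as an energy proxy), ties broken by pose id, and select the top k."""
    if not poses:
        raise ValueError("no poses to rank")
    preds = model.predict(poses)
    order = sorted(range(len(poses)), key=lambda i: (preds[i], poses[i].pose_id))
    ids = [poses[i].pose_id for i in order]
    if k > len(poses):
        logger.warning("requested top %d of only %d poses", k, len(poses))
    selected = ids[: min(k, len(poses))]
    return RankedPoses(pose_ids=ids, predictions=preds[order], selected=selected)


def consensus_binding_residues(
    top_poses: Sequence[Structure],
    cutoff: float = 6.0,
    min_votes: Optional[int] = None,
) -> Tuple[Set[ResidueKey], Set[ResidueKey]]:
    """Residues on each unit's interface in at least ``min_votes`` of the
    given poses (default: a strict majority, ceil(n/2))."""
    if not top_poses:
        raise ValueError("need at least one pose")
    n = len(top_poses)
    votes_rec: Dict[ResidueKey, int] = {}
    votes_lig: Dict[ResidueKey, int] = {}
    if min_votes is None:
        min_votes = math.ceil(n / 2)
    for pose in top_poses:
        rec, lig = interface_residues(contact_pairs(pose, cutoff=cutoff))
        for key in rec:
            votes_rec[key] = votes_rec.get(key, 0) + 1
        for key in lig:
            votes_lig[key] = votes_lig.get(key, 0) + 1
    return (
        {k for k, v in votes_rec.items() if v >= min_votes},
        {k for k, v in votes_lig.items() if v >= min_votes},
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: SvrModel, path) -> None:
    joblib.dump(
        {
            "pipeline": model.pipeline,
            "layout": model.layout,
            "config": model.config,
            "scheme_fingerprints": model.scheme_fingerprints,
            "alphabet_fingerprint": model.alphabet_fingerprint,
        },
        path,
    )


def load_model(
    path,
    sequential_scheme: BlockScheme = DEFAULT_SEQUENTIAL_SCHEME,
    hexagon_scheme: BlockScheme = DEFAULT_HEXAGON_SCHEME,
) -> SvrModel:
    """Load a model and verify its block-scheme and alphabet fingerprints
    against the schemes in use; a mismatch is an error, never a re-map."""
    payload = joblib.load(path)
    expected = (sequential_scheme.fingerprint(), hexagon_scheme.fingerprint())
    if tuple(payload["scheme_fingerprints"]) != expected:
        raise ValueError("model was trained with a different block scheme")
    if payload["alphabet_fingerprint"] != "".join(sorted(AA_INDEX)):
        raise ValueError("model was trained with a different alphabet")
    return SvrModel(
        pipeline=payload["pipeline"],
        layout=tuple(tuple(g) for g in payload["layout"]),
        config=payload["config"],
        scheme_fingerprints=tuple(payload["scheme_fingerprints"]),
        alphabet_fingerprint=payload["alphabet_fingerprint"],
    )


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def run_group_ablation(
    train_rows: Sequence[FeatureGroupVector],
    train_responses: np.ndarray,
    test_rows: Sequence[FeatureGroupVector],
    test_responses: np.ndarray,
    subsets: Mapping[str, Sequence[int]],
    config: SvrConfig = SvrConfig(),
):
    """Train one model per feature-group subset and evaluate held out.

    ``subsets`` maps a label (e.g. ``"multi-scale local"``) to the group ids
    to keep.  Returns a pandas DataFrame with, per subset: number of
    features, held-out mean absolute error, Spearman rank correlation
    between predictions and true responses, and the mean true response of
    the top-10 poses by prediction (the selection-quality analogue of mean
    interface RMSD over selected poses).
    """
    import pandas as pd
    from scipy.stats import spearmanr

    records = []
    for label, group_ids in subsets.items():
        keep = set(group_ids)
        sub_train = [_restrict(r, keep) for r in train_rows]
        sub_test = [_restrict(r, keep) for r in test_rows]
        model = train_svr(TrainingSet(sub_train, train_responses), config)
        preds = model.predict(sub_test)
        order = np.argsort(preds, kind="stable")
        top = order[: min(10, len(order))]
        rho = spearmanr(preds, test_responses).statistic
        records.append(
            {
                "subset": label,
                "groups": ",".join(map(str, sorted(keep))),
                "n_features": sub_train[0].values.size,
                "mae": float(np.mean(np.abs(preds - test_responses))),
                "spearman": float(rho),
                "mean_irmsd_top10": float(np.mean(np.asarray(test_responses)[top])),
            }
        )
    return pd.DataFrame.from_records(records)


def _restrict(row: FeatureGroupVector, keep: Set[int]) -> FeatureGroupVector:
    parts, layout, offset = [], [], 0
    for name, gid, off, length in row.layout:
        if gid not in keep:
            continue
        parts.append(row.values[off : off + length])
        layout.append((name, gid, offset, length))
        offset += length
    if not parts:
        raise ValueError("subset keeps no feature groups")
    return FeatureGroupVector(
        pose_id=row.pose_id, values=np.concatenate(parts), layout=tuple(layout)
    )
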