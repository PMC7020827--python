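"""Index validation: prediction probability (Pk) and leave-one-subject-out CV.

Pk is the probability that the index correctly orders a random pair of
observations by true anesthetic depth: with Pc, Pd and Ptx the pair
probabilities of concordance, discordance and index-only ties (pairs tied in
depth are excluded),

    Pk = (Pc + Ptx/2) / (Pc + Pd + Ptx).

Pk = 1 means perfect ordering, 0.5 chance level; an anticorrelated index
gives Pk < 0.5 and is reported reflected as 1 - Pk.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .model import NetworkSpec, SDAELSTMRegressor

__all__ = ["PkResult", "CVReport", "pk_statistic", "baseline_pk", "loso_cv"]


@dataclass
class PkResult:
    """Pk with its pair decomposition.

    ``pk`` is the reported (reflected) value in [0.5, 1]; ``pk_raw`` the
    unreflected statistic; ``pc``/``pd``/``ptx`` the pair probabilities over
    all unordered pairs (their sum is < 1 when depth ties exist);
    ``n_pairs_used`` counts the depth-distinct pairs in the denominator.
    """

    pk: float
    pk_raw: float
    pc: float
    pd: float
    ptx: float
    n_pairs_used: int
    reflected: bool
    subject_id: str | None = None


def pk_statistic(index, depth, tie_tol: float = 0.0, subject_id: str | None = None) -> PkResult:
    """Prediction probability of ``index`` for true depth ``depth``.

    All unordered pairs with distinct depth are classified: concordant when
    index and depth move the same way, discordant when opposite, index-only
    tie when |delta index| <= tie_tol.  Depth ties use exact equality and
    are excluded.  Raises if every pair is depth-tied.
    """
    x = np.asarray(index, dtype=float).ravel()
    y = np.asarray(depth, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("index and depth must be equal-length arrays of size >= 2")
    if tie_tol < 0:
        raise ValueError("tie_tol must be >= 0")

    n = x.size
    iu, ju = np.triu_indices(n, k=1)
    dx = x[iu] - x[ju]
    dy = y[iu] - y[ju]
    distinct = dy != 0
    x_tied = np.abs(dx) <= tie_tol
    conc = int(np.count_nonzero(distinct & ~x_tied & (dx * dy > 0)))
    disc = int(np.count_nonzero(distinct & ~x_tied & (dx * dy < 0)))
    xtie = int(np.count_nonzero(distinct & x_tied))

    used = conc + disc + xtie
    if used == 0:
        raise ValueError("Pk undefined: all pairs tied in observed depth")
    total = iu.size
    pk_raw = (conc + 0.5 * xtie) / used
    reflected = pk_raw < 0.5
    return PkResult(
        pk=float(1.0 - pk_raw if reflected else pk_raw),
        pk_raw=float(pk_raw),
        pc=conc / total,
        pd=disc / total,
        ptx=xtie / total,
        n_pairs_used=used,
        reflected=bool(reflected),
        subject_id=subject_id,
    )


def baseline_pk(
    features: FeatureMatrix, depth, feature_name: str, tie_tol: float = 0.0
) -> PkResult:
    """Pk of a single raw feature column used directly as the index.

    Entropies fall with depth, so these baselines typically rely on the
    1 - Pk reflection.
    """
    column = features.column(feature_name)
    return pk_statistic(column, depth, tie_tol=tie_tol, subject_id=features.subject_id)


@dataclass
class CVReport:
    """Leave-one-subject-out cross-validation summary.

    ``per_subject_pk`` holds each held-out subject's Pk averaged over
    repeats; ``fold_results`` every individual fold's :class:`PkResult`;
    ``mean``/``sd`` summarize per-subject values (the Table-style
    "mean +- sd over subjects" report).
    """

    per_subject_pk: list[float]
    fold_results: list[PkResult]
    mean: float
    sd: float
    config_hash: str
    skipped: list[str] = field(default_factory=list)


def loso_cv(
    features_per_subject,
    labels_per_subject,
    spec: NetworkSpec | None = None,
    repeats: int = 1,
    seed: int = 0,
) -> CVReport:
    """Leave-one-subject-out cross-validation of the SDAE-LSTM.

    For each repeat and each held-out subject, the network is trained from a
    fresh seed on the remaining subjects (presented in a repeat-specific
    shuffled order), the held-out session is predicted, and Pk of the
    prediction against the subject's effect-site labels is recorded.
    Subjects whose labels are degenerate (all equal) are skipped with a
    warning.  Deterministic given ``seed``.
    """
    spec = spec or NetworkSpec()
    mats = [np.asarray(getattr(f, "values", f), dtype=float) for f in features_per_subject]
    labs = [np.asarray(l, dtype=float) for l in labels_per_subject]
    ids = [
        getattr(f, "subject_id", None) or f"subject{i}"
        for i, f in enumerate(features_per_subject)
    ]
    n_subj = len(mats)
    if n_subj < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")

    fold_results: list[PkResult] = []
    skipped: list[str] = []
    per_subject: dict[int, list[float]] = {i: [] for i in range(n_subj)}
    for rep in range(repeats):
        rep_rng = np.random.default_rng(np.random.SeedSequence([seed, rep]).generate_state(1)[0])
        for test_i in range(n_subj):
            if np.ptp(labs[test_i]) == 0:
                if ids[test_i] not in skipped:
                    warnings.warn(
                        f"skipping fold for {ids[test_i]}: degenerate labels", stacklevel=2
                    )
                    skipped.append(ids[test_i])
                continue
            train_order = [i for i in range(n_subj) if i != test_i]
            rep_rng.shuffle(train_order)
            X = np.vstack([mats[i] for i in train_order])
            y = np.concatenate([labs[i] for i in train_order])
            groups = np.concatenate(
                [np.full(mats[i].shape[0], i) for i in train_order]
            )
            fold_seed = int(
                np.random.SeedSequence([seed, rep, test_i]).generate_state(1)[0] % (2**31)
            )
            reg = SDAELSTMRegressor.from_spec(spec)
            reg.set_params(seed=fold_seed)
            reg.fit(X, y, subjects=groups)
            pred = reg.predict(mats[test_i])
            res = pk_statistic(pred, labs[test_i], subject_id=ids[test_i])
            fold_results.append(res)
            per_subject[test_i].append(res.pk)

    per_subject_pk = [float(np.mean(v)) for v in per_subject.values() if v]
    if not per_subject_pk:
        raise ValueError("no folds could be evaluated")
    config_hash = hashlib.sha1(repr((spec, repeats, seed)).encode()).hexdigest()[:12]
    return CVReport(
        per_subject_pk=per_subject_pk,
        fold_results=fold_results,
        mean=float(np.mean(per_subject_pk)),
        sd=float(np.std(per_subject_pk, ddof=1)) if len(per_subject_pk) > 1 else 0.0,
        config_hash=config_hash,
        skipped=skipped,
    )
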