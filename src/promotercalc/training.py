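"""Fitting the interaction energies from measured promoter datasets.

The training pipeline mirrors how the energies are meant to be used:
measured rates are log-transformed and normalized to the dataset minimum
(``y = ln(TX / TX_min)``), each promoter is reduced to a single binding
configuration (from recorded design annotations, or located by PWM
scanning around the measured TSS), encoded into the 346-entry feature
vector, and a ridge regression with an explicit intercept is fitted with
10-fold cross-validation over the regularization strength.  Because the
model predicts ``y = -beta * dG_total + const``, fitted weights are negated
to obtain energies: favorable motifs get negative values.

One-hot blocks are collinear with the intercept, so reported energies are
centered to mean zero within each categorical block -- the only
identifiable parameterization; the per-block offsets are absorbed into the
reference-rate calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold

from .energy_model import (
    DISC_RANGE,
    FEATURE_NAMES,
    NUMERIC_FEATURES,
    SPACER_RANGE,
    EnergyModelParams,
    FeatureVector,
    InsufficientContextError,
    PromoterConfiguration,
    CompiledModel,
    default_normalizers,
    delta_g_total,
    encode_features,
    parse_configuration,
)
from .shape import ShapeTables, load_default_tables

__all__ = [
    "PromoterDataset",
    "TrainingReport",
    "Pwm",
    "default_pwms",
    "locate_motifs",
    "prepare_targets",
    "build_design_matrix",
    "train_model",
    "feature_drop_analysis",
    "variance_decomposition",
    "fit_interaction_model",
    "positive_control_check",
    "center_blocks",
    "CATEGORICAL_BLOCKS",
    "FEATURE_GROUPS",
]

#: one-hot blocks whose coefficients are only identifiable up to a shift
CATEGORICAL_BLOCKS: dict[str, list[str]] = {
    prefix.rstrip("_"): [n for n in FEATURE_NAMES if n.startswith(prefix)]
    for prefix in ("hex35_1_", "hex35_2_", "hex10_1_", "hex10_2_", "disc_", "ext10_", "spacer_len_")
}

#: named feature groups for drop analysis
FEATURE_GROUPS: dict[str, list[str]] = {
    "hex35": [n for n in FEATURE_NAMES if n.startswith("hex35_")],
    "hex10": [n for n in FEATURE_NAMES if n.startswith("hex10_")],
    "disc": [n for n in FEATURE_NAMES if n.startswith("disc_")],
    "ext10": [n for n in FEATURE_NAMES if n.startswith("ext10_")],
    "spacer_length": [n for n in FEATURE_NAMES if n.startswith("spacer_len_")],
    "spacer_rigidity": ["spacer_rigidity"],
    "up_mgw": ["up_distal_mgw", "up_proximal_mgw"],
    "itr_rloop": ["itr_rloop"],
}

_REQUIRED_COLUMNS = ("id", "sequence", "tss", "tx_mean")


@dataclass
class PromoterDataset:
    """Measured promoters: sequence, predominant TSS and replicate rates.

    ``records`` columns: ``id, sequence, tss`` (0-based predominant TSS),
    ``tx_rep1..k`` replicate rates, ``tx_mean, tx_sd, tx_cv``, optional
    ``split`` ('train'/'test') and optional design annotations
    ``spacer_length, disc_length``.  ``tss_maps`` optionally holds the raw
    TSS read histogram per variant for filtering.
    """

    records: pd.DataFrame
    tss_maps: dict[str, dict[int, int]] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset records missing columns: {missing}")
        if (self.records["tx_mean"] <= 0).any():
            raise ValueError("all transcription rates must be positive")
        if "tx_cv" in self.records.columns and (self.records["tx_cv"].dropna() < 0).any():
            raise ValueError("CV must be non-negative")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def rep_columns(self) -> list[str]:
        return [c for c in self.records.columns if c.startswith("tx_rep")]

    def subset(self, mask) -> "PromoterDataset":
        sub = self.records[mask].reset_index(drop=True)
        maps = None
        if self.tss_maps is not None:
            maps = {i: self.tss_maps[i] for i in sub["id"] if i in self.tss_maps}
        return PromoterDataset(sub, maps)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PromoterDataset":
        return cls(pd.read_csv(path, sep="\t"))


class Pwm:
    """Log-odds position weight matrix over A/C/G/T."""

    def __init__(self, probs: Sequence[Mapping[str, float]]):
        self.log_odds = [
            {b: math.log(p[b] / 0.25) for b in "ACGT"} for p in probs
        ]

    def __len__(self) -> int:
        return len(self.log_odds)

    def score(self, kmer: str) -> float:
        if len(kmer) != len(self.log_odds):
            raise ValueError(f"k-mer length {len(kmer)} != PWM length {len(self.log_odds)}")
        return sum(col[b] for col, b in zip(self.log_odds, kmer))

    @classmethod
    def from_consensus(cls, consensus: str, match: float = 0.7) -> "Pwm":
        """PWM with probability ``match`` on the consensus base, remainder split."""
        off = (1.0 - match) / 3.0
        return cls([{b: (match if b == c else off) for b in "ACGT"} for c in consensus])


def default_pwms() -> dict[str, Pwm]:
    """Consensus-derived PWMs for motif localization (TTGACA / TATAAT)."""
    return {"hex35": Pwm.from_consensus("TTGACA"), "hex10": Pwm.from_consensus("TATAAT")}


def locate_motifs(
    sequence: str,
    tss_index: int,
    pwms: dict[str, Pwm] | None = None,
    spacer_range: range = SPACER_RANGE,
    disc_range: range = DISC_RANGE,
) -> PromoterConfiguration:
    """Locate the hexamers around a known predominant TSS by PWM scanning.

    Enumerates all spacer x disc placements consistent with the TSS, scores
    the implied -35 and -10 hexamers jointly, and returns the
    maximum-scoring configuration.  Score ties are resolved toward the
    optimal 17-nt spacer, then smaller disc, then smaller spacer.
    """
    pwms = pwms or default_pwms()
    order = sorted(
        ((s, d) for s in spacer_range for d in disc_range),
        key=lambda sd: (abs(sd[0] - 17), sd[1], sd[0]),
    )
    best: tuple[float, PromoterConfiguration] | None = None
    for s, d in order:
        try:
            config = parse_configuration(sequence, tss_index, spacer_length=s, disc_length=d)
        except (InsufficientContextError, ValueError):
            continue
        score = pwms["hex35"].score(config.hex35) + pwms["hex10"].score(config.hex10)
        if best is None or score > best[0]:
            best = (score, config)
    if best is None:
        raise InsufficientContextError(
            f"no legal hexamer placement fits around TSS {tss_index} "
            f"(spacer {spacer_range}, disc {disc_range})"
        )
    return best[1]


def prepare_targets(dataset: PromoterDataset) -> tuple[pd.Series, str]:
    """Log-transform and min-normalize rates; pick the reference promoter.

    Returns ``y_i = ln(TX_i / min TX)`` indexed by record id and the id of
    the reference promoter -- the record whose normalized log rate is
    closest to the log-mean-center of the dataset.
    """
    tx = dataset.records["tx_mean"].to_numpy(dtype=float)
    if (tx <= 0).any():
        raise ValueError("non-positive transcription rate")
    y = np.log(tx / tx.min())
    ref_pos = int(np.argmin(np.abs(y - y.mean())))
    return (
        pd.Series(y, index=dataset.records["id"].to_numpy(), name="log_tx"),
        str(dataset.records["id"].iloc[ref_pos]),
    )


def dataset_configurations(
    dataset: PromoterDataset,
    pwms: dict[str, Pwm] | None = None,
) -> list[PromoterConfiguration]:
    """One binding configuration per record.

    Records carrying design annotations (``spacer_length``/``disc_length``)
    are tiled directly at the recorded TSS; others fall back to PWM-based
    motif localization.
    """
    configs: list[PromoterConfiguration] = []
    rec = dataset.records
    annotated = "spacer_length" in rec.columns and "disc_length" in rec.columns
    for row in rec.itertuples(index=False):
        if annotated and not (
            pd.isna(getattr(row, "spacer_length")) or pd.isna(getattr(row, "disc_length"))
        ):
            configs.append(
                parse_configuration(
                    row.sequence,
                    int(row.tss),
                    spacer_length=int(row.spacer_length),
                    disc_length=int(row.disc_length),
                )
            )
        else:
            configs.append(locate_motifs(row.sequence, int(row.tss), pwms))
    return configs


def build_design_matrix(
    dataset: PromoterDataset,
    tables: ShapeTables,
    normalizers: Mapping[str, float],
    configs: Sequence[PromoterConfiguration] | None = None,
) -> np.ndarray:
    """(n x 346) feature matrix in canonical feature order."""
    configs = configs if configs is not None else dataset_configurations(dataset)
    return np.vstack([encode_features(c, tables, normalizers).values for c in configs])


@dataclass
class TrainingReport:
    """Fit diagnostics from :func:`train_model`."""

    chosen_alpha: float
    seed: int
    n_train: int
    n_test: int
    r2_train: float
    r2_test: float
    mae_train: float
    mae_test: float
    mse_train: float
    mse_test: float
    reference_id: str
    learning_curve: list[dict] = field(default_factory=list)
    positive_controls: list[dict] = field(default_factory=list)
    unseen_features: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        import json

        doc = json.dumps(self.__dict__, indent=1, default=float)
        if path is not None:
            Path(path).write_text(doc)
        return doc


def _metrics(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float, float]:
    resid = y - y_hat
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return r2, float(np.abs(resid).mean()), float((resid**2).mean())


def center_blocks(coefficients: Mapping[str, float]) -> dict[str, float]:
    """Center each categorical block of an energy table to mean zero."""
    out = dict(coefficients)
    for names in CATEGORICAL_BLOCKS.values():
        mean = sum(out[n] for n in names) / len(names)
        for n in names:
            out[n] = out[n] - mean
    return out


def train_model(
    dataset: PromoterDataset,
    alphas: Sequence[float] | None = None,
    k_folds: int = 10,
    seed: int = 0,
    tables: ShapeTables | None = None,
    pwms: dict[str, Pwm] | None = None,
    configs: Sequence[PromoterConfiguration] | None = None,
    drop_features: set[str] | None = None,
    learning_curve: bool = True,
) -> tuple[EnergyModelParams, TrainingReport]:
    """Fit the 346 interaction energies by cross-validated ridge regression.

    Parameters
    ----------
    dataset
        Measured promoters.  A ``split`` column ('train'/'test') is honored;
        otherwise a seed-deterministic 90/10 split is drawn.
    alphas
        Regularization grid; defaults to a logarithmic 1e-4..1e2 sweep.
    configs
        Pre-computed binding configurations (bypasses motif localization).
    drop_features
        Feature names excluded from the fit (their energies are set to 0);
        used by :func:`feature_drop_analysis`.
    """
    tables = tables or load_default_tables()
    alphas = list(alphas) if alphas is not None else list(np.logspace(-4, 2, 13))
    rng = np.random.default_rng(seed)

    rec = dataset.records
    if "split" in rec.columns:
        is_train = (rec["split"] == "train").to_numpy()
    else:
        is_train = rng.random(len(rec)) < 0.9
    n_train = int(is_train.sum())
    if n_train < k_folds:
        raise ValueError(f"{k_folds}-fold CV requires at least {k_folds} training records")

    y_all, ref_id = prepare_targets(dataset)
    y = y_all.to_numpy()
    if np.allclose(y, y[0]):
        raise ValueError("all targets identical; nothing to fit")

    normalizers = default_normalizers(tables)
    X = build_design_matrix(dataset, tables, normalizers, configs=configs)

    keep = np.ones(len(FEATURE_NAMES), dtype=bool)
    if drop_features:
        unknown = drop_features - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        keep = np.array([n not in drop_features for n in FEATURE_NAMES])

    Xtr, ytr = X[is_train][:, keep], y[is_train]
    Xte, yte = X[~is_train][:, keep], y[~is_train]

    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        Ridge(fit_intercept=True),
        {"alpha": alphas},
        cv=cv,
        scoring="neg_mean_squared_error",
    )
    search.fit(Xtr, ytr)
    alpha = float(search.best_params_["alpha"])
    model = search.best_estimator_

    # energies: dG contribution = -(fitted weight); unseen levels stay at 0
    w = np.zeros(len(FEATURE_NAMES))
    w[keep] = model.coef_
    observed = X[is_train].sum(axis=0) > 0
    unseen = [n for n, seen, k in zip(FEATURE_NAMES, observed, keep) if k and not seen]
    if unseen:
        warnings.warn(
            f"{len(unseen)} categorical levels unobserved in training; their energies default to 0"
        )
    coefficients = center_blocks({n: -wi for n, wi in zip(FEATURE_NAMES, w)})

    params = EnergyModelParams(
        coefficients=coefficients,
        normalizers=normalizers,
        tx_ref=1.0,
        tables_checksum=tables.checksum(),
    )
    # calibrate tx_ref so predicted rates line up with the min-normalized scale
    w_dg = np.array([coefficients[n] for n in FEATURE_NAMES])
    dg_train = X[is_train] @ w_dg
    params.tx_ref = float(np.exp(np.mean(ytr + dg_train)))

    predict = lambda Xm: np.log(params.tx_ref) - (Xm @ w_dg)  # noqa: E731
    r2_tr, mae_tr, mse_tr = _metrics(ytr, predict(X[is_train]))
    if len(yte):
        r2_te, mae_te, mse_te = _metrics(yte, predict(X[~is_train]))
    else:
        r2_te = mae_te = mse_te = float("nan")

    curve: list[dict] = []
    if learning_curve and n_train >= 20:
        for frac in (0.25, 0.5, 0.75, 1.0):
            m = max(int(frac * n_train), k_folds)
            idx = rng.permutation(n_train)[:m]
            sub = Ridge(alpha=alpha, fit_intercept=True).fit(Xtr[idx], ytr[idx])
            curve.append(
                {
                    "n_train": m,
                    "train_mae": float(np.abs(ytr[idx] - sub.predict(Xtr[idx])).mean()),
                    "test_mae": float(np.abs(yte - sub.predict(Xte)).mean())
                    if len(yte)
                    else float("nan"),
                }
            )

    report = TrainingReport(
        chosen_alpha=alpha,
        seed=seed,
        n_train=n_train,
        n_test=int((~is_train).sum()),
        r2_train=r2_tr,
        r2_test=r2_te,
        mae_train=mae_tr,
        mae_test=mae_te,
        mse_train=mse_tr,
        mse_test=mse_te,
        reference_id=ref_id,
        learning_curve=curve,
        positive_controls=positive_control_check(params),
        unseen_features=unseen,
    )
    return params, report


def feature_drop_analysis(
    dataset: PromoterDataset,
    groups: Sequence[str] | None = None,
    tolerance: float = 0.02,
    **train_kwargs,
) -> pd.DataFrame:
    """Retrain without each feature group and report the test-MAE change.

    A positive ``delta_test_mae`` means the group carries signal; groups
    whose removal changes the test MAE by at most ``tolerance`` are marked
    prunable.
    """
    groups = list(groups) if groups is not None else list(FEATURE_GROUPS)
    unknown = [g for g in groups if g not in FEATURE_GROUPS]
    if unknown:
        raise ValueError(f"unknown feature groups: {unknown}")
    _, baseline = train_model(dataset, learning_curve=False, **train_kwargs)
    rows = []
    for group in groups:
        _, rep = train_model(
            dataset,
            drop_features=set(FEATURE_GROUPS[group]),
            learning_curve=False,
            **train_kwargs,
        )
        delta = rep.mae_test - baseline.mae_test
        rows.append(
            {
                "group": group,
                "n_features": len(FEATURE_GROUPS[group]),
                "baseline_test_mae": baseline.mae_test,
                "dropped_test_mae": rep.mae_test,
                "delta_test_mae": delta,
                "prunable": abs(delta) <= tolerance,
            }
        )
    return pd.DataFrame(rows)


_TERM_ORDER = ("dg_up", "dg_35", "dg_spacer", "dg_10ext", "dg_10", "dg_disc", "dg_itr")


def variance_decomposition(
    params: EnergyModelParams,
    dataset: PromoterDataset,
    tables: ShapeTables | None = None,
    configs: Sequence[PromoterConfiguration] | None = None,
) -> dict[str, float]:
    """ANOVA-style attribution of measured rate variance to the energy terms.

    Sequential sums of squares: terms are added in fixed order
    (UP, -35, spacer, -10ext, -10, disc, ITR) to an intercept-only model of
    the measured log rates; each term's fraction is its incremental
    explained sum of squares over the total.  Fractions plus the residual
    sum to 1.  Terms constant across the dataset contribute 0.
    """
    tables = tables or load_default_tables()
    compiled = CompiledModel(params, tables)
    configs = configs if configs is not None else dataset_configurations(dataset)
    y, _ = prepare_targets(dataset)
    y = y.to_numpy()
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero-variance dataset")

    term_values = {t: [] for t in _TERM_ORDER}
    for config in configs:
        bd = compiled.breakdown(config)
        for t in _TERM_ORDER:
            term_values[t].append(getattr(bd, t))

    columns = [np.ones(len(y))]
    rss_prev = ss_tot
    fractions: dict[str, float] = {}
    for t in _TERM_ORDER:
        col = np.array(term_values[t])
        if np.allclose(col, col[0]):
            fractions[t] = 0.0
            continue
        columns.append(col)
        design = np.column_stack(columns)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((y - design @ coef) ** 2).sum())
        fractions[t] = (rss_prev - rss) / ss_tot
        rss_prev = rss
    fractions["residual"] = rss_prev / ss_tot
    return fractions


@dataclass
class InteractionModelReport:
    """Quadratic inter-motif extension of the linear energy model."""

    interaction_coefficients: dict[str, float]
    linear_coefficients: dict[str, float]
    intercept: float
    rank_deficient: bool
    metrics: dict[str, dict[str, float]]  # {"linear"/"interaction"} x {train/test r2/mae/mse}

    @property
    def n_interaction_coefficients(self) -> int:
        return len(self.interaction_coefficients)


_REGIONS = ("up", "hex35", "spacer", "hex10", "disc", "itr")
# spacer region folds in the extended -10, which lives at the spacer's 3' end
_REGION_TERMS = {
    "up": ("dg_up",),
    "hex35": ("dg_35",),
    "spacer": ("dg_spacer", "dg_10ext"),
    "hex10": ("dg_10",),
    "disc": ("dg_disc",),
    "itr": ("dg_itr",),
}


def fit_interaction_model(
    dataset: PromoterDataset,
    params: EnergyModelParams,
    tables: ShapeTables | None = None,
    configs: Sequence[PromoterConfiguration] | None = None,
    seed: int = 0,
) -> InteractionModelReport:
    """Augment the six region energies with all 30 ordered pairwise products.

    The per-record region energies are computed from the trained linear
    model; a least-squares fit (minimum-norm pseudo-inverse when the design
    is rank deficient, which ordered duplicate products guarantee) adds the
    6 x 5 interaction coefficients.  Metrics are reported against the
    linear-terms-only baseline on the same split.
    """
    tables = tables or load_default_tables()
    compiled = CompiledModel(params, tables)
    configs = configs if configs is not None else dataset_configurations(dataset)
    y, _ = prepare_targets(dataset)
    y = y.to_numpy()

    E = np.empty((len(configs), len(_REGIONS)))
    for i, config in enumerate(configs):
        bd = compiled.breakdown(config)
        for j, region in enumerate(_REGIONS):
            E[i, j] = sum(getattr(bd, t) for t in _REGION_TERMS[region])

    pair_names = [
        f"{a}*{b}" for a in _REGIONS for b in _REGIONS if a != b
    ]
    pairs = np.column_stack(
        [E[:, i] * E[:, j] for i in range(6) for j in range(6) if i != j]
    )
    assert pairs.shape[1] == 30

    rec = dataset.records
    if "split" in rec.columns:
        is_train = (rec["split"] == "train").to_numpy()
    else:
        is_train = np.random.default_rng(seed).random(len(rec)) < 0.9

    def fit_eval(Xm: np.ndarray) -> tuple[np.ndarray, float, bool, dict[str, dict[str, float]]]:
        design = np.column_stack([np.ones(len(y)), Xm])
        dtr = design[is_train]
        coef, _, rank, _ = np.linalg.lstsq(dtr, y[is_train], rcond=None)
        deficient = rank < design.shape[1]
        out = {}
        for label, mask in (("train", is_train), ("test", ~is_train)):
            if mask.sum() == 0:
                out[label] = {"r2": float("nan"), "mae": float("nan"), "mse": float("nan")}
                continue
            r2, mae, mse = _metrics(y[mask], design[mask] @ coef)
            out[label] = {"r2": r2, "mae": mae, "mse": mse}
        return coef, float(coef[0]), deficient, out

    _, _, _, lin_metrics = fit_eval(E)
    coef, intercept, deficient, int_metrics = fit_eval(np.column_stack([E, pairs]))
    if deficient:
        warnings.warn("interaction design is rank deficient; minimum-norm solution used")

    return InteractionModelReport(
        interaction_coefficients=dict(zip(pair_names, map(float, coef[7:]))),
        linear_coefficients=dict(zip(_REGIONS, map(float, coef[1:7]))),
        intercept=intercept,
        rank_deficient=deficient,
        metrics={"linear": lin_metrics, "interaction": int_metrics},
    )


def positive_control_check(params: EnergyModelParams) -> list[dict]:
    """Check that canonical motifs carry the most favorable trained energies.

    Four report-only controls: the TTGACA 3-mers are jointly minimal within
    the -35 blocks, TATAAT within the -10 blocks, TG within the extended
    -10 2-mers, and the 17-bp spacer among the length bits.  A non-unique
    minimum is reported as a tie (fail).
    """
    w = params.coefficients
    checks = [
        ("hex35_TTGACA", [("hex35_1_", "TTG"), ("hex35_2_", "ACA")]),
        ("hex10_TATAAT", [("hex10_1_", "TAT"), ("hex10_2_", "AAT")]),
        ("ext10_TG", [("ext10_", "TG")]),
        ("spacer_17", [("spacer_len_", "17")]),
    ]
    results = []
    for name, parts in checks:
        passed, reason = True, "canonical feature uniquely minimal"
        for prefix, canonical in parts:
            block = {k: v for k, v in w.items() if k.startswith(prefix)}
            target = f"{prefix}{canonical}"
            minimum = min(block.values())
            argmins = [k for k, v in block.items() if v == minimum]
            if argmins != [target]:
                passed = False
                reason = (
                    f"tie at minimum: {sorted(argmins)[:4]}"
                    if target in argmins
                    else f"minimum is {argmins[0]}, not {target}"
                )
                break
        results.append({"control": name, "passed": passed, "reason": reason})
    return results
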