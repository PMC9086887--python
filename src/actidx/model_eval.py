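"""Leave-one-participant-out classification, diagnostic metrics, chi-square.

Evaluation follows the diagnostic-study design: one fold per participant
(LOPO cross-validation, so no child's data is ever shared between training
and testing), a random-forest classifier (default 2000 trees; a "stumps"
mode restricts trees to depth 1), and three feature configurations:

* ``motion_only`` — whole-day motion features;
* ``motion_plus_context`` — whole-day motion plus contextual-sensor
  features (heart rate, GPS, Bluetooth);
* ``motion_plus_labels`` — motion features additionally stratified by the
  parent-reported activity context.

Per configuration the per-participant predictions are reduced to a 2x2
confusion table (hyperactive group = positive class), the five diagnostic
ratios, and a 1-df Pearson chi-square test against chance (no continuity
correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .features import (
    FeatureConfig,
    FeatureMatrix,
    MOTION_FAMILIES,
    SENSOR_FAMILIES,
    WHOLE_DAY,
    build_feature_matrix,
)
from .sensor_io import StudyDataset, UsageError
from .selection import POSITIVE_CLASS, SelectionConfig, stability_scores

CONFIGURATIONS = ("motion_only", "motion_plus_context", "motion_plus_labels")


class DegenerateTableError(ValueError):
    """A confusion table with a zero marginal (expected cell of 0)."""


@dataclass(frozen=True)
class ModelConfig:
    n_trees: int = 2000
    max_depth: int | None = None  # None = unrestricted; 1 = decision stumps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise UsageError("n_trees must be >= 1")


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts with the hyperactive group as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise UsageError("confusion counts must be nonnegative")
        if self.n < 1:
            raise UsageError("confusion table must count at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fn, self.fp, self.tn)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy, sensitivity, specificity, PPV, NPV; None when undefined."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


def lopo_folds(matrix: FeatureMatrix) -> list[tuple[pd.Index, str]]:
    """One fold per participant: (training ids, held-out id)."""
    ids = matrix.values.index
    if len(ids) < 2:
        raise UsageError("need at least 2 participants for LOPO")
    if matrix.groups.nunique() < 2:
        raise UsageError("need both classes in the dataset")
    return [(ids.drop(pid), pid) for pid in ids]


def _fold_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def fit_predict(
    train_x: pd.DataFrame,
    train_y: pd.Series,
    test_x: pd.DataFrame,
    config: ModelConfig,
) -> tuple[str, float]:
    """Balanced random-forest prediction for one held-out participant.

    An ensemble of ``n_trees`` randomized decision trees: each tree trains
    on a class-stratified bootstrap (an equal number of participants
    resampled with replacement from each class) with sqrt(p) feature
    subsampling at splits. The stratified bootstrap matters under LOPO:
    every training fold is one participant short in the held-out child's
    class, and with a plain bootstrap that count difference alone tilts the
    vote toward the majority class, biasing null-data accuracy below
    chance. The score is the fraction of trees voting for the positive
    class; the threshold is 0.5 with ties broken toward control (the
    conservative call). Training rows are canonicalized by participant id
    so the prediction is invariant to their order.
    """
    if train_y.nunique() < 2:
        raise UsageError("training fold contains a single class")
    order = np.argsort(np.asarray(train_x.index, dtype=object), kind="stable")
    x = train_x.to_numpy(dtype=float)[order]
    y = (np.asarray(train_y)[order] == POSITIVE_CLASS).astype(int)
    xt = test_x.to_numpy(dtype=float)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    n_draw = min(idx_pos.size, idx_neg.size)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    tree_seeds = rng.integers(2**31 - 1, size=config.n_trees)
    votes = 0
    for b in range(config.n_trees):
        rows = np.concatenate(
            [
                rng.choice(idx_pos, size=n_draw, replace=True),
                rng.choice(idx_neg, size=n_draw, replace=True),
            ]
        )
        tree = DecisionTreeClassifier(
            max_depth=config.max_depth,
            max_features="sqrt",
            random_state=int(tree_seeds[b]),
        )
        tree.fit(x[rows], y[rows])
        votes += int(tree.predict(xt)[0] == 1)
    score = votes / config.n_trees
    predicted = POSITIVE_CLASS if score > 0.5 else "control"
    return predicted, float(score)


def confusion_from_predictions(
    truth: Sequence[str], predicted: Sequence[str]
) -> ConfusionTable:
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise UsageError("truth and prediction vectors differ in length")
    tp = sum(t == POSITIVE_CLASS and p == POSITIVE_CLASS for t, p in zip(truth, predicted))
    fn = sum(t == POSITIVE_CLASS and p != POSITIVE_CLASS for t, p in zip(truth, predicted))
    fp = sum(t != POSITIVE_CLASS and p == POSITIVE_CLASS for t, p in zip(truth, predicted))
    tn = sum(t != POSITIVE_CLASS and p != POSITIVE_CLASS for t, p in zip(truth, predicted))
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def diagnostic_metrics(table: ConfusionTable) -> DiagnosticMetrics:
    """The five diagnostic ratios; undefined ratios are None, never 0."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return DiagnosticMetrics(
        accuracy=(table.tp + table.tn) / table.n,
        sensitivity=ratio(table.tp, table.tp + table.fn),
        specificity=ratio(table.tn, table.tn + table.fp),
        ppv=ratio(table.tp, table.tp + table.fp),
        npv=ratio(table.tn, table.tn + table.fn),
    )


def pearson_chi_square(table: ConfusionTable) -> tuple[float, float, int]:
    """1-df Pearson chi-square of the 2x2 table, without continuity correction.

    statistic = N (TP*TN - FN*FP)^2 / ((TP+FN)(FP+TN)(TP+FP)(FN+TN)).
    Raises DegenerateTableError when a marginal (hence an expected cell) is 0.
    """
    tp, fn, fp, tn = table.as_tuple()
    margins = ((tp + fn), (fp + tn), (tp + fp), (fn + tn))
    if any(m == 0 for m in margins):
        raise DegenerateTableError("zero marginal: expected cell count of 0")
    num = table.n * (tp * tn - fn * fp) ** 2
    den = margins[0] * margins[1] * margins[2] * margins[3]
    statistic = num / den
    p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p_value, 1


def reconstruct_tables(
    n_pos: int,
    n_neg: int,
    printed: dict[str, float],
    ndigits: int = 2,
) -> list[ConfusionTable]:
    """All 2x2 tables with fixed group sizes matching printed metrics.

    Exhaustively enumerates TP in 0..n_pos and TN in 0..n_neg and keeps the
    tables whose five diagnostic ratios round (half-away-from-zero, as
    printed) to the supplied values. Lets a report's rounded metric table be
    inverted back to the underlying integer confusion table.
    """

    def printed_round(v: float | None) -> float | None:
        if v is None:
            return None
        return float(np.floor(v * 10**ndigits + 0.5) / 10**ndigits)

    hits = []
    for tp in range(n_pos + 1):
        for tn in range(n_neg + 1):
            table = ConfusionTable(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)
            m = diagnostic_metrics(table)
            got = {
                "accuracy": printed_round(m.accuracy),
                "sensitivity": printed_round(m.sensitivity),
                "specificity": printed_round(m.specificity),
                "ppv": printed_round(m.ppv),
                "npv": printed_round(m.npv),
            }
            if all(got[k] == printed[k] for k in printed):
                hits.append(table)
    return hits


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


def columns_for_configuration(columns: Iterable[str], configuration: str) -> list[str]:
    """Feature-matrix column block visible to one model configuration."""
    if configuration not in CONFIGURATIONS:
        raise UsageError(f"unknown configuration {configuration!r}")
    out = []
    for col in columns:
        family, _, _, _, context, _ = col.split("__")
        is_motion = family in MOTION_FAMILIES
        if configuration == "motion_only":
            keep = is_motion and context == WHOLE_DAY
        elif configuration == "motion_plus_labels":
            keep = is_motion
        else:  # motion_plus_context
            keep = (is_motion and context == WHOLE_DAY) or family in SENSOR_FAMILIES
        if keep:
            out.append(col)
    return out


@dataclass
class ConfigurationOutcome:
    configuration: str
    table: ConfusionTable
    metrics: DiagnosticMetrics
    chi_square: float | None
    p_value: float | None
    predictions: pd.DataFrame  # participant_id, group, score, prediction, fold
    selected_features: list[str]  # global selection, or union over folds


@dataclass
class ExperimentResult:
    outcomes: dict[str, ConfigurationOutcome]
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, oc in self.outcomes.items():
            r = {"configuration": name}
            r.update(oc.metrics.rounded())
            r["chi_square"] = None if oc.chi_square is None else round(oc.chi_square, 2)
            r["p_value"] = None if oc.p_value is None else round(oc.p_value, 4)
            rows.append(r)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {"seed": self.seed, "configurations": {}}
        for name, oc in self.outcomes.items():
            out["configurations"][name] = {
                "confusion": {
                    "TP": oc.table.tp,
                    "FN": oc.table.fn,
                    "FP": oc.table.fp,
                    "TN": oc.table.tn,
                },
                "metrics": oc.metrics.__dict__,
                "chi_square": oc.chi_square,
                "p_value": oc.p_value,
                "selected_features": oc.selected_features,
            }
        return out

    def to_markdown(self) -> str:
        lines = [
            "| Model | Accuracy | Sensitivity | Specificity | PPV | NPV | chi2(1) | P |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for name, oc in self.outcomes.items():
            m = oc.metrics.rounded()

            def fmt(v):
                return "—" if v is None else f"{v:.2f}"

            chi = "—" if oc.chi_square is None else f"{oc.chi_square:.2f}"
            p = "—" if oc.p_value is None else f"{oc.p_value:.3f}"
            lines.append(
                f"| {name} | {fmt(m['accuracy'])} | {fmt(m['sensitivity'])} | "
                f"{fmt(m['specificity'])} | {fmt(m['ppv'])} | {fmt(m['npv'])} | {chi} | {p} |"
            )
        return "\n".join(lines) + "\n"


def evaluate_configuration(
    matrix: FeatureMatrix,
    configuration: str,
    model_config: ModelConfig,
    selection_config: SelectionConfig,
    selection_mode: str = "inside",
) -> ConfigurationOutcome:
    """LOPO evaluation of one feature configuration.

    ``selection_mode="inside"`` reruns stability selection on every training
    fold (no information from the held-out child reaches the selector);
    ``"outside"`` selects once on the full matrix before cross-validation,
    the simpler global variant.
    """
    if selection_mode not in ("inside", "outside"):
        raise UsageError("selection_mode must be 'inside' or 'outside'")
    cols = columns_for_configuration(matrix.values.columns, configuration)
    x = matrix.values[cols]
    y = matrix.groups

    global_selected: list[str] | None = None
    if selection_mode == "outside":
        result = stability_scores(x, y, selection_config)
        global_selected = result.retained

    records = []
    union_selected: set[str] = set()
    for fold_idx, (train_ids, test_id) in enumerate(lopo_folds(matrix)):
        if selection_mode == "inside":
            fold_sel = stability_scores(
                x.loc[train_ids],
                y.loc[train_ids],
                SelectionConfig(
                    **{
                        **selection_config.__dict__,
                        "seed": _fold_seed(selection_config.seed, fold_idx),
                    }
                ),
            )
            selected = fold_sel.retained
        else:
            selected = global_selected
        union_selected.update(selected)
        fold_model = ModelConfig(
            n_trees=model_config.n_trees,
            max_depth=model_config.max_depth,
            seed=_fold_seed(model_config.seed, fold_idx),
        )
        predicted, score = fit_predict(
            x.loc[train_ids, selected],
            y.loc[train_ids],
            x.loc[[test_id], selected],
            fold_model,
        )
        records.append(
            {
                "participant_id": test_id,
                "group": y.loc[test_id],
                "configuration": configuration,
                "score": score,
                "prediction": predicted,
                "fold": fold_idx,
            }
        )
    predictions = pd.DataFrame(records)
    table = confusion_from_predictions(predictions["group"], predictions["prediction"])
    metrics = diagnostic_metrics(table)
    try:
        chi, p, _ = pearson_chi_square(table)
    except DegenerateTableError:
        chi, p = None, None
    selected_out = (
        global_selected if selection_mode == "outside" else sorted(union_selected)
    )
    return ConfigurationOutcome(
        configuration=configuration,
        table=table,
        metrics=metrics,
        chi_square=chi,
        p_value=p,
        predictions=predictions,
        selected_features=selected_out,
    )


def run_experiment(
    dataset: StudyDataset,
    configurations: Sequence[str] = CONFIGURATIONS,
    selection_config: SelectionConfig | None = None,
    model_config: ModelConfig | None = None,
    feature_config: FeatureConfig | None = None,
    selection_mode: str = "inside",
) -> ExperimentResult:
    """Filter-agnostic experiment driver: features -> selection -> LOPO.

    Expects an already day-filtered dataset. The full feature matrix is
    built once; each configuration sees only its column block.
    """
    selection_config = selection_config or SelectionConfig()
    model_config = model_config or ModelConfig()
    feature_config = feature_config or FeatureConfig(include_context_sensors=True)
    matrix = build_feature_matrix(dataset, feature_config)
    outcomes = {}
    for configuration in configurations:
        outcomes[configuration] = evaluate_configuration(
            matrix, configuration, model_config, selection_config, selection_mode
        )
    return ExperimentResult(outcomes=outcomes, seed=model_config.seed)
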