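"""Hold-out validation protocol and repeated-experiment aggregation.

One experiment: shuffle the dataset with a run seed, take the first 70% for
training (floor rounding, not stratified), build the atom-environment
vocabulary on the training fold only and freeze it, train the classifier,
then score the held-out fold and compute the full metrics report.  Repeating
this with consecutive seeds and averaging the per-run precision / recall /
F1 / AUC gives the summary table; the mean row uses the same two-decimal
(percent) and four-decimal (AUC) rounding as the per-run reports.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .chem_io import LabeledRecord, parse_smiles, SmilesParseError
from .gcn_model import TrainConfig, train, predict_batch
from .graph_build import AtomVocabulary, encode_graph
from .metrics import MetricsReport, ROCCurve, evaluate, roc_curve, write_report, write_roc_points

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ExperimentResult:
    run: int
    report: MetricsReport
    loss_trace: tuple[float, ...]
    n_train: int
    n_test: int
    roc: ROCCurve | None = None


@dataclass(frozen=True)
class ExperimentTable:
    results: tuple[ExperimentResult, ...]
    mean_precision: float
    mean_recall: float
    mean_f1: float
    mean_auc: float | None


def holdout_split(records: list[LabeledRecord], spec: SplitSpec
                  ) -> tuple[list[LabeledRecord], list[LabeledRecord]]:
    """Seeded uniform random split; train gets the first floor(fraction*n).

    Deliberately not stratified by class, so per-run class balance varies.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(records))
    n_train = int(np.floor(spec.train_fraction * len(records)))
    if n_train == 0 or n_train == len(records):
        raise ValueError("split produced an empty fold")
    train_recs = [records[i] for i in order[:n_train]]
    test_recs = [records[i] for i in order[n_train:]]
    return train_recs, test_recs


def _drop_unparseable(records: list[LabeledRecord]) -> list[LabeledRecord]:
    kept = []
    dropped = 0
    for rec in records:
        try:
            parse_smiles(rec.smiles)
        except SmilesParseError:
            dropped += 1
            logger.warning("dropping unparseable SMILES: %s", rec.smiles)
            continue
        kept.append(rec)
    if dropped:
        logger.warning("dropped %d unparseable record(s)", dropped)
    return kept


def run_experiment(records: list[LabeledRecord], config: TrainConfig,
                   run_seed: int, run_index: int = 0) -> ExperimentResult:
    """One hold-out run: split, train-fold vocabulary, train, evaluate."""
    records = _drop_unparseable(records)
    train_recs, test_recs = holdout_split(
        records, SplitSpec(train_fraction=config.train_fraction, seed=run_seed))

    vocab = AtomVocabulary()
    for rec in train_recs:  # vocabulary from the training fold only
        encode_graph(parse_smiles(rec.smiles), vocab, config.radius)
    vocab.freeze()

    run_config = replace(config, seed=run_seed)
    params, loss_trace = train(train_recs, vocab, run_config)

    predictions, failures = predict_batch(test_recs, vocab, params, run_config)
    assert not failures  # unparseable records were dropped before splitting
    labels = [rec.label for rec in test_recs]
    predicted = [p.label for p in predictions]
    scores = [p.score for p in predictions]
    report = evaluate(labels, predicted, scores)
    roc = None
    if report.auc is None:
        logger.warning("run %d: single-class test fold, AUC missing", run_index)
    else:
        roc = roc_curve(labels, scores)
    return ExperimentResult(run=run_index, report=report,
                            loss_trace=tuple(loss_trace),
                            n_train=len(train_recs), n_test=len(test_recs),
                            roc=roc)


def mean_row(rows: list[tuple[float, float, float, float | None]]
             ) -> tuple[float, float, float, float | None]:
    """Arithmetic mean of per-run (precision, recall, f1, auc) rows.

    Rounded like the reports: two decimals for the percentages, four for AUC.
    Runs whose AUC is missing are excluded from the AUC mean only.
    """
    if not rows:
        raise ValueError("no rows to aggregate")
    aucs = [row[3] for row in rows if row[3] is not None]
    return (
        round(float(np.mean([row[0] for row in rows])), 2),
        round(float(np.mean([row[1] for row in rows])), 2),
        round(float(np.mean([row[2] for row in rows])), 2),
        round(float(np.mean(aucs)), 4) if aucs else None,
    )


def aggregate(results: list[ExperimentResult]) -> ExperimentTable:
    """Mean row over per-run metrics, at report rounding (2 dp / 4 dp)."""
    if not results:
        raise ValueError("no results to aggregate")
    mp, mr, mf, ma = mean_row(
        [(r.report.precision, r.report.recall, r.report.f1, r.report.auc)
         for r in results])
    return ExperimentTable(results=tuple(results), mean_precision=mp,
                           mean_recall=mr, mean_f1=mf, mean_auc=ma)


def run_many(records: list[LabeledRecord], config: TrainConfig,
             n_runs: int) -> ExperimentTable:
    """Repeat the hold-out experiment with run seeds = base seed + index."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = [
        run_experiment(records, config, run_seed=config.seed + i, run_index=i + 1)
        for i in range(n_runs)
    ]
    return aggregate(results)


def summarize(table: ExperimentTable, outdir: str | Path) -> None:
    """Write the per-run metrics CSV (with mean row) and loss traces."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        (str(r.run), r.report.precision, r.report.recall, r.report.f1, r.report.auc)
        for r in table.results
    ]
    rows.append(("mean", table.mean_precision, table.mean_recall,
                 table.mean_f1, table.mean_auc))
    write_report(rows, outdir / "metrics.csv")
    for r in table.results:
        if r.roc is not None:
            write_roc_points(r.roc, outdir / f"roc_run{r.run}.csv")
    for r in table.results:
        with (outdir / f"loss_run{r.run}.csv").open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "loss"])
            for i, loss in enumerate(r.loss_trace, start=1):
                writer.writerow([i, f"{loss:.8f}"])
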