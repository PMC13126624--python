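"""Repeated-seed experiment orchestration.

``run_experiment`` wires the full protocol: for every repetition seed it
splits the dataset under the chosen scenario, fits the selected models,
generates a ranked candidate list per test compound, sweeps the number of
emitted codes k, scores every (model, k) cell with both metric families and
finally aggregates mean and standard deviation across seeds.  All
randomness is derived from the per-repetition seed, so a config is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atc import CompoundRecord
from .baselines import fit_level_distribution, random_predict
from .chem import DescriptorMatrix, fit_apply_standardization
from .metrics import LEVELS, EvaluationInstance, compute_level_metrics
from .seq2seq import Seq2SeqConfig, beam_generate, train_seq2seq
from .splits import SplitResult, new_drug_split, repurposing_split


@dataclass
class ExperimentConfig:
    scenario: str = "newdrug"  # "newdrug" | "repurposing"
    seeds: tuple[int, ...] = tuple(range(10))
    models: tuple[str, ...] = ("bilstm",)  # bilstm|transformer|m.bilstm|m.transformer|random
    k_sweep: tuple[int, ...] = (1,)
    beam_width: int = 10
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    val_fraction: float = 0.1
    seq2seq: Seq2SeqConfig = field(default_factory=Seq2SeqConfig)

    def __post_init__(self) -> None:
        if self.scenario not in ("newdrug", "repurposing"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class ExperimentReport:
    """Per-seed metric reports and cross-seed aggregation."""

    config: ExperimentConfig
    per_seed: dict[int, dict[str, dict[int, "object"]]]  # seed→model→k→report

    def aggregated(self) -> pd.DataFrame:
        """Mean/std per (model, k, metric) over seeds.

        Undefined levels (no evaluated compounds) are excluded from a
        metric's averaging denominator.
        """
        rows = []
        models = self.config.models
        for model in models:
            for k in self.config.k_sweep:
                metrics: dict[str, list[float]] = {}
                for seed_reports in self.per_seed.values():
                    rep = seed_reports[model][k]
                    for n in LEVELS:
                        if rep.l_precision[n] is not None:
                            metrics.setdefault(f"l_precision_{n}", []).append(
                                rep.l_precision[n]
                            )
                            metrics.setdefault(f"l_recall_{n}", []).append(
                                rep.l_recall[n]
                            )
                    metrics.setdefault("precision", []).append(rep.exact_precision)
                    metrics.setdefault("recall", []).append(rep.exact_recall)
                    metrics.setdefault("f1", []).append(rep.exact_f1)
                for name, vals in metrics.items():
                    rows.append(
                        {
                            "model": model,
                            "k": k,
                            "metric": name,
                            "mean": float(np.mean(vals)),
                            "std": float(np.std(vals)),
                            "n_seeds": len(vals),
                        }
                    )
        return pd.DataFrame(rows)


def _split(config: ExperimentConfig, records, seed) -> SplitResult:
    if config.scenario == "newdrug":
        return new_drug_split(records, config.ratios, seed)
    return repurposing_split(records, config.val_fraction, seed)


def _standardized_descriptors(
    records: list[CompoundRecord],
    matrix: DescriptorMatrix | None,
    train_ids: set[str],
) -> dict[str, np.ndarray] | None:
    if matrix is None:
        return None
    fit_rows = [i for i, r in enumerate(records) if r.compound_id in train_ids]
    std = fit_apply_standardization(matrix, fit_rows)
    kept = std.kept_values()
    return {r.compound_id: kept[i] for i, r in enumerate(records)}


def run_experiment(
    config: ExperimentConfig,
    records: list[CompoundRecord],
    descriptors: DescriptorMatrix | None = None,
) -> ExperimentReport:
    """Execute the repeated-seed protocol and return the scored report."""
    if not records:
        raise ValueError("empty dataset")
    needs_desc = any(m.startswith("m.") for m in config.models)
    if needs_desc and descriptors is None:
        raise ValueError("multimodal models require a descriptor matrix")
    per_seed: dict[int, dict[str, dict[int, object]]] = {}
    for seed in config.seeds:
        split = _split(config, records, seed)
        train_ids = {r.compound_id for r in split.train}
        desc = _standardized_descriptors(records, descriptors, train_ids)
        seed_reports: dict[str, dict[int, object]] = {}
        for model_name in config.models:
            try:
                cand_lists = _candidates_for(
                    model_name, config, split, desc, seed
                )
            except Exception as exc:
                raise RuntimeError(
                    f"model {model_name!r} failed at seed {seed}"
                ) from exc
            seed_reports[model_name] = {}
            for k in config.k_sweep:
                instances = [
                    EvaluationInstance(
                        predicted=list(cands[:k]), actual=rec.code_strings()
                    )
                    for rec, cands in zip(split.test, cand_lists)
                ]
                seed_reports[model_name][k] = compute_level_metrics(instances)
        per_seed[seed] = seed_reports
    return ExperimentReport(config=config, per_seed=per_seed)


def _candidates_for(model_name, config, split, desc, seed) -> list[list[str]]:
    """Ranked candidate code strings (length max(k_sweep)) per test compound."""
    k_max = max(config.k_sweep)
    if model_name == "random":
        dist = fit_level_distribution(split.train + split.validation)
        return [
            random_predict(dist, seed=seed * 100003 + i, k=k_max)
            for i in range(len(split.test))
        ]
    multimodal = model_name.startswith("m.")
    arch = model_name.removeprefix("m.")
    s2s = replace(config.seq2seq, architecture=arch, multimodal=multimodal, seed=seed)
    model = train_seq2seq(
        split.train, split.validation, s2s, descriptors=desc if multimodal else None
    )
    return [
        [
            c.code_string
            for c in beam_generate(
                model,
                rec.smiles,
                desc[rec.compound_id] if multimodal else None,
                beam_width=max(config.beam_width, k_max),
                k=k_max,
            )
        ]
        for rec in split.test
    ]
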