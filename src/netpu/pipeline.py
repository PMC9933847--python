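"""Stage runner chaining simulate -> features -> label -> classify / discover.

Each stage reads the TSV/JSON artifacts of its predecessors from a working
directory and writes its own, with a header comment recording version and
parameters; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .classify import (cross_validate, evaluate_ranking, mask_and_rediscover,
                       pooled_mean_sd, rank_candidates, train_eval)
from .config import RunConfig
from .features import FeatureMatrix, assemble_features
from .labeling import LABELS, LabelAssignment, label_genes
from .network import Network, SeedSet, load_network, load_seeds, write_network, write_seeds
from .synth import generate

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "STAGES", "read_features_tsv", "read_labels_tsv",
           "write_features_tsv", "write_labels_tsv"]

STAGES = ("simulate", "features", "label", "classify", "discover")

_DEPS = {
    "features": [("network.tsv", "simulate"), ("seeds.tsv", "simulate")],
    "label": [("features.tsv", "features"), ("seeds.tsv", "simulate")],
    "classify": [("features.tsv", "features"), ("labels.tsv", "label")],
    "discover": [("network.tsv", "simulate"), ("seeds.tsv", "simulate")],
}


def _header(cfg: RunConfig, keys: Sequence[str]) -> str:
    params = " ".join(f"{k}={getattr(cfg, k)}" for k in keys)
    return f"# netpu {__version__} {params}\n"


def write_features_tsv(F: FeatureMatrix, path: Path, header: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("gene\t" + "\t".join(F.columns) + "\n")
        for i, g in enumerate(F.order):
            fh.write(g + "\t" + "\t".join(f"{v:.12g}" for v in F.X[i]) + "\n")


def read_features_tsv(path: Path) -> FeatureMatrix:
    order, rows, columns = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if columns is None:
                columns = tuple(parts[1:])
                continue
            order.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return FeatureMatrix(order=tuple(order), columns=columns, X=np.array(rows))


def write_labels_tsv(assignment: LabelAssignment, path: Path, header: str = "") -> None:
    rank = {g: i + 1 for i, g in enumerate(assignment.ranking)}
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("gene\tlabel\tg_inf\trank\n")
        for g in sorted(assignment.label):
            fh.write(f"{g}\t{assignment.label[g]}\t{assignment.g_inf[g]:.12g}\t"
                     f"{rank.get(g, 0)}\n")


def read_labels_tsv(path: Path) -> LabelAssignment:
    label, g_inf, rank = {}, {}, {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("gene\t"):
                continue
            g, cls, val, rk = line.rstrip("\n").split("\t")
            label[g], g_inf[g] = cls, float(val)
            if int(rk):
                rank[g] = int(rk)
    ranking = tuple(sorted(rank, key=lambda g: rank[g]))
    return LabelAssignment(label=label, ranking=ranking, g_inf=g_inf,
                           fractions=(1 / 3, 1 / 3, 1 / 3))


def _require(outdir: Path, stage: str) -> None:
    for artifact, producer in _DEPS.get(stage, []):
        if not (outdir / artifact).exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {artifact}; run stage {producer!r} first")


def run_pipeline(
    cfg: RunConfig,
    stages: Sequence[str] = STAGES,
    outdir: str | Path = ".",
    *,
    network_path: str | Path | None = None,
    seeds_path: str | Path | None = None,
    gold_path: str | Path | None = None,
) -> dict[str, Path]:
    """Run the requested stages, writing artifacts into ``outdir``.

    ``network_path``/``seeds_path`` substitute real input files for the
    simulate stage.  Returns a map of artifact name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in set(stages)]
    artifacts: dict[str, Path] = {}
    logger.info("effective config: %s", cfg.to_dict())

    if "simulate" in stages:
        inst = generate(n=cfg.n, module_size=cfg.module_size, p_in=cfg.p_in,
                        p_out=cfg.p_out, hidden_fraction=cfg.hidden_fraction,
                        score_dist=(cfg.score_low, cfg.score_high), rng_seed=cfg.seed)
        write_network(inst.net, outdir / "network.tsv")
        write_seeds(inst.visible_seeds, outdir / "seeds.tsv")
        with open(outdir / "hidden.tsv", "w") as fh:
            fh.write("gene\n")
            for g in sorted(inst.hidden_positives):
                fh.write(g + "\n")
        artifacts |= {k: outdir / f"{k}.tsv" for k in ("network", "seeds", "hidden")}
    elif network_path or seeds_path:
        # copy external inputs into the working dir so later stages find them
        if network_path:
            write_network(load_network(network_path), outdir / "network.tsv")
        if seeds_path:
            net = load_network(outdir / "network.tsv", header=True)
            write_seeds(load_seeds(seeds_path, net), outdir / "seeds.tsv")

    if "features" in stages:
        _require(outdir, "features")
        net = load_network(outdir / "network.tsv", header=True)
        seeds = load_seeds(outdir / "seeds.tsv", net, header=True)
        F = assemble_features(net, seeds, t_heat=cfg.t_heat, t_balanced=cfg.t_balanced,
                              penalization=cfg.penalization, mixing=cfg.mixing,
                              invert_netring=cfg.invert_netring)
        write_features_tsv(F, outdir / "features.tsv",
                           _header(cfg, ["t_heat", "t_balanced", "penalization", "mixing"]))
        artifacts["features"] = outdir / "features.tsv"

    if "label" in stages:
        _require(outdir, "label")
        F = read_features_tsv(outdir / "features.tsv")
        net = load_network(outdir / "network.tsv", header=True)
        seeds = load_seeds(outdir / "seeds.tsv", net, header=True)
        assignment = label_genes(F, seeds.members, q_w=cfg.q_w, alpha=cfg.alpha,
                                 tol=cfg.tol, max_iter=cfg.max_iter,
                                 n_rn=cfg.rn_size, fractions=cfg.fractions)
        write_labels_tsv(assignment, outdir / "labels.tsv",
                         _header(cfg, ["alpha", "q_w", "tol", "fractions"]))
        artifacts["labels"] = outdir / "labels.tsv"

    if "classify" in stages:
        _require(outdir, "classify")
        F = read_features_tsv(outdir / "features.tsv")
        assignment = read_labels_tsv(outdir / "labels.tsv")
        report = train_eval(F, assignment, model=cfg.model,
                            test_fraction=cfg.test_fraction, seed=cfg.seed)
        cv_reports = cross_validate(F, assignment, model=cfg.model, k=cfg.cv,
                                    seed=cfg.seed)
        payload = {"holdout": report.to_dict(),
                   "cv_pooled": pooled_mean_sd(cv_reports)}
        with open(outdir / "eval_report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "confusion.tsv", "w") as fh:
            fh.write(_header(cfg, ["model", "test_fraction", "seed"]))
            fh.write("true\\pred\t" + "\t".join(LABELS) + "\n")
            for i, c in enumerate(LABELS):
                fh.write(c + "\t" + "\t".join(str(int(v)) for v in report.confusion[i]) + "\n")
        artifacts["eval_report"] = outdir / "eval_report.json"
        artifacts["confusion"] = outdir / "confusion.tsv"

    if "discover" in stages:
        _require(outdir, "discover")
        net = load_network(outdir / "network.tsv", header=True)
        seeds = load_seeds(outdir / "seeds.tsv", net, header=True)
        feature_params = dict(t_heat=cfg.t_heat, t_balanced=cfg.t_balanced,
                              penalization=cfg.penalization, mixing=cfg.mixing,
                              invert_netring=cfg.invert_netring)
        label_params = dict(q_w=cfg.q_w, alpha=cfg.alpha, tol=cfg.tol,
                            max_iter=cfg.max_iter, n_rn=cfg.rn_size,
                            fractions=cfg.fractions)
        if gold_path is None and (outdir / "hidden.tsv").exists():
            gold_path = outdir / "hidden.tsv"
        rep = mask_and_rediscover(net, seeds, cfg.mask_fraction, cfg.n_folds,
                                  seed=cfg.seed, feature_params=feature_params,
                                  label_params=label_params)
        with open(outdir / "rediscovery.tsv", "w") as fh:
            fh.write(_header(cfg, ["mask_fraction", "n_folds", "seed"]))
            fh.write("fold\t" + "\t".join(LABELS) + "\n")
            for i, fold in enumerate(rep.per_fold):
                fh.write(str(i) + "\t" + "\t".join(str(fold[c]) for c in LABELS) + "\n")
            fh.write("total\t" + "\t".join(str(rep.total_counts()[c]) for c in LABELS) + "\n")
        artifacts["rediscovery"] = outdir / "rediscovery.tsv"
        if gold_path is not None:
            with open(gold_path) as fh:
                gold = {ln.strip() for ln in fh
                        if ln.strip() and not ln.startswith("#") and ln.strip() != "gene"}
            F = assemble_features(net, seeds, **feature_params)
            assignment = label_genes(F, seeds.members, **label_params)
            ranking = rank_candidates(assignment)
            ks = sorted({max(1, int(round(frac * len(gold))))
                         for frac in (0.1, 0.25, 0.5, 1.0, 2.0)})
            rows = evaluate_ranking(ranking, gold, ks)
            with open(outdir / "ranking_f1.tsv", "w") as fh:
                fh.write(_header(cfg, ["q_w", "alpha", "seed"]))
                fh.write("k\tprecision\trecall\tf1\n")
                for k, p, r, f1 in rows:
                    fh.write(f"{k}\t{p:.12g}\t{r:.12g}\t{f1:.12g}\n")
            artifacts["ranking_f1"] = outdir / "ranking_f1.tsv"

    return artifacts
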