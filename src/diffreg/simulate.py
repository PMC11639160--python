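"""Synthetic equivalence-class data with known ground truth.

The generator samples directly from the model's generative structure at
desk scale: group-level splice proportions pi_bar per feature, a shared
log-normal precision delta_plus, per-sample proportions from the
hierarchical Beta/Dirichlet law, per-sample feature abundances rho, and
multinomial read counts.  Quantification uncertainty is injected at the EC
level: a configurable fraction of reads is emitted into multi-member ECs
whose extra members come from a fixed random compatibility pool, standing
in for the homology structure of a real transcriptome.

Differential regulation (DR) is injected by swapping the S and U components
of pi_bar in one randomly chosen group; differential gene expression (DGE)
— a nuisance effect the method should *not* detect — multiplies the
rho-weights of a disjoint feature subset by a fold change in one group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ec_data import (
    BULK,
    SINGLE_CELL,
    ECDataset,
    EquivalenceClass,
    FeatureIndex,
    SpliceStatus,
    merge_classes,
)

DEFAULT_PI_BAR_ALPHA = {BULK: (6.0, 2.0), SINGLE_CELL: (6.0, 2.0, 2.0)}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale two-group bulk experiment: 200 features,
    3 biological replicates per group, 1e5 reads per sample, 20% of reads
    emitted into multi-member ECs, 20% DR features, DGE off.  The unspliced
    baseline fraction averages 0.25 (pi_bar ~ Dirichlet(6, 2)) and the
    between-sample precision is log-normal around delta_plus ~ 33
    (log delta_plus ~ Normal(3.5, 0.5)), typical of biological replicates.
    """

    mode: str = BULK
    n_features: int = 200
    n_samples_per_group: int = 3
    reads_per_sample: int = 100_000
    rho_concentration: float = 1.0
    log_prec_mu: float = 3.5
    log_prec_sd: float = 0.5
    pi_bar_alpha: tuple[float, ...] | None = None
    fraction_dr: float = 0.2
    fraction_dge: float = 0.2
    dge_fold_change: float = 0.0  # 0 = off; typical nuisance strengths are 3, 6 or 9
    multimap_rate: float = 0.2
    max_members: int = 3
    compat_rounds: int = 2  # independent random partitions into compatibility sets
    length_log_mean: float = float(np.log(1500.0))
    length_log_sd: float = 0.2
    unspliced_length_factor: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (BULK, SINGLE_CELL):
            raise ValueError(f"unknown mode {self.mode!r}")
        for frac in (self.fraction_dr, self.fraction_dge, self.multimap_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.dge_fold_change != 0.0 and self.dge_fold_change < 1.0:
            raise ValueError("dge_fold_change must be 0 (off) or >= 1")
        if self.reads_per_sample <= 0 or self.n_features <= 0:
            raise ValueError("reads_per_sample and n_features must be positive")
        if self.max_members < 2:
            raise ValueError("max_members must be >= 2")
        if self.pi_bar_alpha is None:
            self.pi_bar_alpha = DEFAULT_PI_BAR_ALPHA[self.mode]
        if len(self.pi_bar_alpha) != (2 if self.mode == BULK else 3):
            raise ValueError("pi_bar_alpha length must match the mode's status count")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pi_bar_alpha"] = list(self.pi_bar_alpha)
        return d


@dataclass
class SimTruth:
    """Ground-truth parameters and labels of a simulated dataset."""

    feature_ids: list[str]
    pi_bar: dict[str, np.ndarray]  # group -> (F, K)
    delta_plus: np.ndarray  # (F,)
    is_dr: np.ndarray  # (F,) bool
    dr_group: np.ndarray  # (F,) object, group whose pi_bar was inverted ('' if none)
    dge_fold: np.ndarray  # (F,) applied fold change (1 = none)
    dge_group: np.ndarray
    rho: dict[str, np.ndarray]  # group -> (F,)
    mode: str

    def pi_tilde_u(self, group: str) -> np.ndarray:
        pb = self.pi_bar[group]
        if self.mode == BULK:
            return pb[:, 1]
        return pb[:, 1] + 0.5 * pb[:, 2]

    def to_frame(self) -> pd.DataFrame:
        data = {
            "feature_id": self.feature_ids,
            "delta_plus": self.delta_plus,
            "is_dr": self.is_dr,
            "dr_group": self.dr_group,
            "dge_fold": self.dge_fold,
            "dge_group": self.dge_group,
        }
        statuses = "SU" if self.mode == BULK else "SUA"
        for g in ("A", "B"):
            for k, s in enumerate(statuses):
                data[f"pi_bar_{s}_{g}"] = self.pi_bar[g][:, k]
            data[f"rho_{g}"] = self.rho[g]
        return pd.DataFrame(data)


def _build_compat_pool(config: SimConfig, rng: np.random.Generator) -> tuple[list[tuple], np.ndarray]:
    """Fixed random compatibility pool emulating transcriptome homology.

    Each of ``compat_rounds`` rounds randomly partitions all (feature,
    status) slots into member sets of size 2..max_members.  A multi-mapping
    read from any member of a set is emitted into that set's EC, so the
    compatibility channel is symmetric — as it is for sequence-driven ECs,
    where every read compatible with the same members lands in the same
    class.  Returns the pool and a (F*K, rounds) array mapping each slot to
    its set per round.
    """
    n_stat = 2 if config.mode == BULK else 3
    n_slots = config.n_features * n_stat
    pool: list[tuple] = []
    slot_to_set = np.zeros((n_slots, config.compat_rounds), dtype=np.int64)
    for r in range(config.compat_rounds):
        order = rng.permutation(n_slots)
        pos = 0
        while pos < n_slots:
            size = int(rng.integers(2, config.max_members + 1))
            chunk = order[pos : pos + size]
            if len(chunk) < 2:  # a trailing singleton joins the previous set
                pool[-1] = tuple(sorted(set(pool[-1]) | {(int(chunk[0]) // n_stat,
                                                          int(chunk[0]) % n_stat)}))
                slot_to_set[chunk, r] = len(pool) - 1
                break
            members = tuple(sorted({(int(s) // n_stat, int(s) % n_stat) for s in chunk}))
            pool.append(members)
            slot_to_set[chunk, r] = len(pool) - 1
            pos += size
    return pool, slot_to_set


def simulate_dataset(config: SimConfig) -> tuple[ECDataset, SimTruth]:
    """Generate one two-group EC dataset plus its ground truth.

    Per-sample EC totals equal ``reads_per_sample`` exactly and the whole
    procedure is byte-reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_feat, n_stat = config.n_features, (2 if config.mode == BULK else 3)
    feature_ids = [f"F{i:05d}" for i in range(n_feat)]

    # group-level proportions, DR inversion
    pi_bar0 = rng.dirichlet(np.asarray(config.pi_bar_alpha), size=n_feat)
    n_dr = int(round(config.fraction_dr * n_feat))
    dr_idx = rng.choice(n_feat, size=n_dr, replace=False) if n_dr else np.empty(0, int)
    dr_flip = rng.choice(["A", "B"], size=n_dr)
    pi_bar = {"A": pi_bar0.copy(), "B": pi_bar0.copy()}
    is_dr = np.zeros(n_feat, dtype=bool)
    dr_group = np.array([""] * n_feat, dtype=object)
    for f, g in zip(dr_idx, dr_flip):
        pi_bar[g][f, [0, 1]] = pi_bar[g][f, [1, 0]]
        is_dr[f] = True
        dr_group[f] = g

    delta_plus = np.exp(rng.normal(config.log_prec_mu, config.log_prec_sd, size=n_feat))

    # feature abundances, DGE on a disjoint subset
    w = rng.dirichlet(np.full(n_feat, config.rho_concentration))
    rho = {"A": w.copy(), "B": w.copy()}
    dge_fold = np.ones(n_feat)
    dge_group = np.array([""] * n_feat, dtype=object)
    if config.dge_fold_change > 0:
        candidates = np.setdiff1d(np.arange(n_feat), dr_idx)
        n_dge = min(int(round(config.fraction_dge * n_feat)), len(candidates))
        dge_idx = rng.choice(candidates, size=n_dge, replace=False)
        dge_flip = rng.choice(["A", "B"], size=n_dge)
        for f, g in zip(dge_idx, dge_flip):
            rho[g][f] *= config.dge_fold_change
            dge_fold[f] = config.dge_fold_change
            dge_group[f] = g
        for g in ("A", "B"):
            rho[g] = rho[g] / rho[g].sum()

    if config.mode == BULK:
        eff_len_s = np.exp(rng.normal(config.length_log_mean, config.length_log_sd, n_feat))
        eff_len_u = eff_len_s * config.unspliced_length_factor * np.exp(
            rng.normal(0.0, 0.1, n_feat)
        )
        fidx = FeatureIndex(tuple(feature_ids), BULK, eff_len_s, eff_len_u)
    else:
        fidx = FeatureIndex(tuple(feature_ids), SINGLE_CELL)

    pool, slot_to_set = _build_compat_pool(config, rng)

    sample_ids: list[str] = []
    group_labels: list[str] = []
    classes: list[list[EquivalenceClass]] = []
    for group in ("A", "B"):
        alpha = pi_bar[group] * delta_plus[:, None]  # (F, K)
        for i in range(config.n_samples_per_group):
            sample_ids.append(f"{group}{i + 1}")
            group_labels.append(group)
            g = rng.standard_gamma(alpha)
            g = np.clip(g, 1e-300, None)
            pi_i = g / g.sum(axis=1, keepdims=True)
            p = (rho[group][:, None] * pi_i).ravel()
            counts = rng.multinomial(config.reads_per_sample, p / p.sum()).reshape(n_feat, n_stat)
            ecs: dict[tuple, int] = {}
            for f, k in zip(*np.nonzero(counts)):
                c = int(counts[f, k])
                n_amb = rng.binomial(c, config.multimap_rate) if config.multimap_rate > 0 else 0
                if c - n_amb > 0:
                    key = ((int(f), SpliceStatus(int(k))),)
                    ecs[key] = ecs.get(key, 0) + (c - n_amb)
                if n_amb:
                    split = rng.multinomial(n_amb, np.full(config.compat_rounds,
                                                          1.0 / config.compat_rounds))
                    slot = int(f) * n_stat + int(k)
                    for r, n_r in enumerate(split):
                        if n_r == 0:
                            continue
                        members = pool[slot_to_set[slot, r]]
                        key = tuple((int(pf), SpliceStatus(int(ps))) for pf, ps in members)
                        ecs[key] = ecs.get(key, 0) + int(n_r)
            classes.append(
                merge_classes(EquivalenceClass(m, c) for m, c in ecs.items())
            )

    dataset = ECDataset(
        feature_index=fidx,
        sample_ids=sample_ids,
        classes=classes,
        group_labels=list(group_labels),
    )
    truth = SimTruth(
        feature_ids=feature_ids,
        pi_bar=pi_bar,
        delta_plus=delta_plus,
        is_dr=is_dr,
        dr_group=dr_group,
        dge_fold=dge_fold,
        dge_group=dge_group,
        rho=rho,
        mode=config.mode,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Ranking evaluation
# ---------------------------------------------------------------------------

def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_ranking(
    results: pd.DataFrame,
    truth: SimTruth,
    top_n: tuple[int, ...] = (10, 20, 50, 100, 200),
) -> dict:
    """AUROC and top-N false-positive counts of both rankings against DR labels.

    Scores: ``rank_score`` for the posterior-probability ranking and
    ``1 - wald_pvalue`` for the Wald ranking.  Degenerate truth (all or no
    DR among the analyzed features) yields None AUROCs.
    """
    truth_df = truth.to_frame().set_index("feature_id")
    merged = results.join(truth_df[["is_dr"]], on="feature_id", how="inner")
    labels = merged["is_dr"].to_numpy(bool)
    out: dict = {"n_features": len(merged), "n_dr": int(labels.sum())}
    if labels.all() or not labels.any():
        out["auroc_prob"] = out["auroc_wald"] = None
        out["fp_top_n"] = {}
        return out
    out["auroc_prob"] = _auroc(merged["rank_score"].to_numpy(), labels)
    out["auroc_wald"] = _auroc(1.0 - merged["wald_pvalue"].to_numpy(), labels)
    ordered = merged.sort_values(
        ["rank_score", "cluster_id", "feature_id"],
        ascending=[False, True, True], kind="mergesort",
    )
    ordered_labels = ordered["is_dr"].to_numpy(bool)
    out["fp_top_n"] = {
        int(n): int((~ordered_labels[:n]).sum()) for n in top_n if n <= len(ordered_labels)
    }
    return out


# ---------------------------------------------------------------------------
# On-disk representation
# ---------------------------------------------------------------------------

def write_dataset(outdir: str | Path, dataset: ECDataset, truth: SimTruth | None = None,
                  config: SimConfig | None = None) -> None:
    """Write a simulated dataset: per-sample EC TSVs, feature index, groups, truth."""
    import yaml

    from .ec_data import write_ec_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.feature_index.to_tsv(outdir / "features.tsv")
    for i, sid in enumerate(dataset.sample_ids):
        write_ec_tsv(outdir / f"{sid}.ec.tsv", dataset, i)
    pd.DataFrame(
        {"sample": dataset.sample_ids, "group": dataset.group_labels}
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if config is not None:
        (outdir / "sim_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
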