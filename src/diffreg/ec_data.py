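"""Equivalence-class (EC) data structures, on-disk formats and pre-analysis filtering.

An equivalence class is the set of reads compatible with exactly the same
collection of (feature, splice-status) pairs, where a feature is a transcript
(bulk data) or a gene (single-cell data) and the splice status is spliced (S),
unspliced (U) or — in single-cell data only — ambiguous (A, compatible with
both splice versions of the same gene).  ECs and their read counts are the
observed data of the model; everything downstream consumes the canonicalized
representation built here.

Supported on-disk formats:

* portable EC TSV, one file per sample: lines ``count<TAB>members`` with
  ``members`` a comma-separated list of ``featureID|S`` / ``|U`` / ``|A``
  tokens; ``#`` starts a comment;
* salmon ``eq_classes.txt`` (plain, non-bootstrap variant), with unspliced
  transcripts marked by a configurable name suffix (default ``-U``);
* MatrixMarket spliced/unspliced/ambiguous (USA) gene-by-cell counts plus a
  barcode -> (sample, cluster) map, aggregated to per-cluster pseudo-bulk.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("diffreg")

BULK = "bulk"
SINGLE_CELL = "single-cell"

GROUP_LABELS = ("A", "B")


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class SpliceStatus(enum.IntEnum):
    """Splice status of the reads in an EC member.

    ``A`` (ambiguous between the spliced and unspliced version of one gene)
    is only legal in single-cell mode.
    """

    S = 0
    U = 1
    A = 2

    @classmethod
    def parse(cls, token: str) -> "SpliceStatus":
        try:
            return cls[token]
        except KeyError:
            raise InputError(f"unknown splice status {token!r} (expected S, U or A)") from None


def n_statuses(mode: str) -> int:
    if mode == BULK:
        return 2
    if mode == SINGLE_CELL:
        return 3
    raise InputError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class FeatureIndex:
    """Ordered feature identifiers plus (bulk only) effective lengths.

    The ordering of ``ids`` defines the integer feature indices used
    everywhere downstream.  In bulk mode each feature carries strictly
    positive effective lengths for its spliced and unspliced versions,
    used to length-normalize the read-allocation weights.
    """

    ids: tuple[str, ...]
    mode: str
    eff_len_S: np.ndarray | None = None
    eff_len_U: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in (BULK, SINGLE_CELL):
            raise InputError(f"unknown mode {self.mode!r}")
        if len(self.ids) == 0:
            raise InputError("feature index is empty")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("feature ids are not unique")
        if any((not isinstance(i, str)) or i == "" for i in self.ids):
            raise InputError("feature ids must be non-empty strings")
        for name in ("eff_len_S", "eff_len_U"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(self.ids),) or not np.all(arr > 0):
                    raise InputError(f"{name} must be positive with one entry per feature")
                object.__setattr__(self, name, arr)
        object.__setattr__(self, "_pos", {fid: i for i, fid in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_statuses(self) -> int:
        return n_statuses(self.mode)

    def index_of(self, feature_id: str) -> int:
        try:
            return self._pos[feature_id]  # type: ignore[attr-defined]
        except KeyError:
            raise InputError(f"unknown feature id {feature_id!r}") from None

    def eff_len_matrix(self) -> np.ndarray:
        """(F, 2) array of effective lengths, columns ordered S, U (bulk only)."""
        if self.mode != BULK:
            raise InputError("effective lengths are a bulk-mode concept")
        if self.eff_len_S is None or self.eff_len_U is None:
            raise InputError("feature index has no effective lengths (column eff_len_S/eff_len_U)")
        return np.column_stack([self.eff_len_S, self.eff_len_U])

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str) -> "FeatureIndex":
        """Read a feature-index TSV: ``feature_id[, eff_len_S, eff_len_U]``."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if "feature_id" not in df.columns:
            # headerless single column of ids
            df = pd.read_csv(path, sep="\t", comment="#", header=None)
            df.columns = ["feature_id"] + [f"col{i}" for i in range(1, df.shape[1])]
        ids = tuple(str(x) for x in df["feature_id"])
        if mode == BULK:
            for col in ("eff_len_S", "eff_len_U"):
                if col not in df.columns:
                    raise InputError(f"bulk feature index {path} is missing column {col!r}")
            return cls(ids, BULK, df["eff_len_S"].to_numpy(float), df["eff_len_U"].to_numpy(float))
        return cls(ids, SINGLE_CELL)

    def to_tsv(self, path: str | Path) -> None:
        data: dict[str, object] = {"feature_id": list(self.ids)}
        if self.eff_len_S is not None:
            data["eff_len_S"] = self.eff_len_S
            data["eff_len_U"] = self.eff_len_U
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EquivalenceClass:
    """A canonical (member-set, count) pair.

    ``members`` is sorted by (feature index, status) and contains no
    duplicates; ``count`` is a non-negative integer number of reads.
    """

    members: tuple[tuple[int, SpliceStatus], ...]
    count: int

    def __post_init__(self) -> None:
        members = tuple(sorted((int(f), SpliceStatus(s)) for f, s in self.members))
        if len(members) == 0:
            raise InputError("equivalence class with empty member set")
        if len(set(members)) != len(members):
            raise InputError(f"duplicate members in equivalence class: {members}")
        if not isinstance(self.count, (int, np.integer)) or self.count < 0:
            raise InputError(f"EC count must be a non-negative integer, got {self.count!r}")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "count", int(self.count))

    @property
    def features(self) -> tuple[int, ...]:
        """Distinct feature indices touched by this class."""
        return tuple(sorted({f for f, _ in self.members}))


def merge_classes(classes: Iterable[EquivalenceClass]) -> list[EquivalenceClass]:
    """Merge duplicate member-sets (summing counts) and sort canonically."""
    acc: dict[tuple[tuple[int, SpliceStatus], ...], int] = {}
    for ec in classes:
        acc[ec.members] = acc.get(ec.members, 0) + ec.count
    return [EquivalenceClass(m, c) for m, c in sorted(acc.items())]


@dataclass
class ECDataset:
    """Per-sample equivalence classes over a shared feature index.

    ``classes[i]`` is the canonical EC list of sample ``sample_ids[i]``;
    ``group_labels[i]`` is "A", "B" or None (not yet assigned).
    """

    feature_index: FeatureIndex
    sample_ids: list[str]
    classes: list[list[EquivalenceClass]]
    group_labels: list[str | None] = field(default_factory=list)
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not self.group_labels:
            self.group_labels = [None] * len(self.sample_ids)
        if not (len(self.sample_ids) == len(self.classes) == len(self.group_labels)):
            raise InputError("sample_ids, classes and group_labels must align")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample ids")
        nf, ns = len(self.feature_index), self.feature_index.n_statuses
        for sample_classes in self.classes:
            for ec in sample_classes:
                for f, s in ec.members:
                    if not 0 <= f < nf:
                        raise InputError(f"EC member feature index {f} out of range")
                    if int(s) >= ns:
                        raise InputError(
                            f"status {SpliceStatus(s).name} is illegal in {self.feature_index.mode} mode"
                        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def mode(self) -> str:
        return self.feature_index.mode

    def total_count(self, sample: int) -> int:
        return sum(ec.count for ec in self.classes[sample])

    def with_groups(self, groups: Mapping[str, str]) -> "ECDataset":
        """Return a copy with group labels assigned from a sample -> group map."""
        labels: list[str | None] = []
        for sid in self.sample_ids:
            if sid not in groups:
                raise InputError(f"sample {sid!r} has no group assignment")
            g = groups[sid]
            if g not in GROUP_LABELS:
                raise InputError(f"group label {g!r} for sample {sid!r} (expected A or B)")
            labels.append(g)
        return replace(self, group_labels=labels)

    def samples_in_group(self, group: str) -> list[int]:
        return [i for i, g in enumerate(self.group_labels) if g == group]

    def subset_samples(self, indices: Sequence[int]) -> "ECDataset":
        return ECDataset(
            feature_index=self.feature_index,
            sample_ids=[self.sample_ids[i] for i in indices],
            classes=[self.classes[i] for i in indices],
            group_labels=[self.group_labels[i] for i in indices],
            cluster_id=self.cluster_id,
        )

    @classmethod
    def concat(cls, parts: Sequence["ECDataset"]) -> "ECDataset":
        """Concatenate single-sample datasets sharing one feature index."""
        first = parts[0]
        for p in parts[1:]:
            if p.feature_index.ids != first.feature_index.ids or p.mode != first.mode:
                raise InputError("cannot concatenate datasets with different feature indices")
        return cls(
            feature_index=first.feature_index,
            sample_ids=[s for p in parts for s in p.sample_ids],
            classes=[c for p in parts for c in p.classes],
            group_labels=[g for p in parts for g in p.group_labels],
            cluster_id=first.cluster_id,
        )


@dataclass
class LatentCounts:
    """Latent allocation X: per sample and feature, read counts per status.

    ``x`` has shape (n_samples, n_features, n_statuses); ``y`` is the
    status-summed per-feature total.  The grand total per sample equals the
    sample's EC count total — allocation never creates or loses reads.
    """

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        if self.x.ndim != 3 or not np.issubdtype(self.x.dtype, np.integer):
            raise InputError("LatentCounts.x must be an integer (N, F, K) array")
        if np.any(self.x < 0):
            raise InputError("negative latent counts")

    @property
    def y(self) -> np.ndarray:
        return self.x.sum(axis=2)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_member_token(token: str, feature_index: FeatureIndex) -> tuple[int, SpliceStatus]:
    if "|" not in token:
        raise InputError(f"malformed member token {token!r} (expected featureID|status)")
    fid, _, status = token.rpartition("|")
    s = SpliceStatus.parse(status)
    if feature_index.mode == BULK and s == SpliceStatus.A:
        raise InputError(f"status A in member {token!r} is illegal in bulk mode")
    return feature_index.index_of(fid), s


def read_ec_tsv(
    path: str | Path,
    feature_index: FeatureIndex,
    sample_id: str | None = None,
) -> ECDataset:
    """Read one sample's ECs from the portable TSV dialect.

    Duplicate member-sets are merged with summed counts and members are
    sorted canonically; the total read count is preserved.
    """
    path = Path(path)
    classes: list[EquivalenceClass] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 'count<TAB>members', got {raw!r}")
        count_str, member_str = parts
        try:
            count = int(count_str)
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-integer count {count_str!r}") from None
        if count < 0:
            raise InputError(f"{path}:{lineno}: negative count {count}")
        members = tuple(
            _parse_member_token(tok.strip(), feature_index)
            for tok in member_str.split(",")
            if tok.strip() != ""
        )
        if not members:
            raise InputError(f"{path}:{lineno}: empty member list")
        classes.append(EquivalenceClass(members, count))
    return ECDataset(
        feature_index=feature_index,
        sample_ids=[sample_id or path.stem],
        classes=[merge_classes(classes)],
    )


def write_ec_tsv(path: str | Path, dataset: ECDataset, sample: int = 0) -> None:
    """Write one sample of a dataset in the portable EC TSV dialect."""
    ids = dataset.feature_index.ids
    lines = ["# diffreg portable EC TSV"]
    for ec in merge_classes(dataset.classes[sample]):
        members = ",".join(f"{ids[f]}|{SpliceStatus(s).name}" for f, s in ec.members)
        lines.append(f"{ec.count}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_salmon_eq_classes(
    path: str | Path,
    unspliced_suffix: str = "-U",
    feature_index: FeatureIndex | None = None,
    sample_id: str | None = None,
) -> ECDataset:
    """Read a salmon ``eq_classes.txt`` file (plain, non-bootstrap layout).

    Transcript names carrying ``unspliced_suffix`` collapse onto the base
    name with status U; names without it get status S.  If ``feature_index``
    is None an index (without effective lengths) is built from the collapsed
    names in first-appearance order.
    """
    path = Path(path)
    tokens = [t for t in path.read_text(encoding="utf-8").split("\n") if t.strip() != ""]
    if len(tokens) < 2:
        raise InputError(f"{path}: truncated eq_classes file")
    try:
        n_names, n_classes = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise InputError(f"{path}: header must be two integer lines") from None
    if len(tokens) != 2 + n_names + n_classes:
        raise InputError(
            f"{path}: expected {2 + n_names + n_classes} lines for N={n_names}, M={n_classes}, "
            f"found {len(tokens)}"
        )
    names = [t.strip() for t in tokens[2 : 2 + n_names]]

    def collapse(name: str) -> tuple[str, SpliceStatus]:
        if unspliced_suffix and name.endswith(unspliced_suffix):
            return name[: -len(unspliced_suffix)], SpliceStatus.U
        return name, SpliceStatus.S

    collapsed = [collapse(n) for n in names]
    if feature_index is None:
        seen: dict[str, None] = {}
        for fid, _ in collapsed:
            seen.setdefault(fid)
        feature_index = FeatureIndex(tuple(seen), BULK)
    name_to_member = [(feature_index.index_of(fid), s) for fid, s in collapsed]

    classes: list[EquivalenceClass] = []
    for lineno, line in enumerate(tokens[2 + n_names :], start=3 + n_names):
        fields = line.split()
        try:
            ints = [int(x) for x in fields]
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-integer token in class line") from None
        if len(ints) < 3:
            raise InputError(f"{path}:{lineno}: malformed class line")
        k, ids, count = ints[0], ints[1:-1], ints[-1]
        if len(ids) != k:
            raise InputError(f"{path}:{lineno}: class arity {k} but {len(ids)} transcript ids")
        if count < 0:
            raise InputError(f"{path}:{lineno}: negative count {count}")
        members: set[tuple[int, SpliceStatus]] = set()
        for tid in ids:
            if not 0 <= tid < n_names:
                raise InputError(f"{path}:{lineno}: transcript id {tid} out of range")
            members.add(name_to_member[tid])
        classes.append(EquivalenceClass(tuple(members), count))
    return ECDataset(
        feature_index=feature_index,
        sample_ids=[sample_id or path.stem],
        classes=[merge_classes(classes)],
    )


def read_usa_mtx(
    mtx_path: str | Path,
    rows_path: str | Path,
    cols_path: str | Path,
    barcode_cluster_map: str | Path | pd.DataFrame,
) -> tuple[list[ECDataset], int]:
    """Aggregate USA gene-by-cell counts into per-cluster pseudo-bulk datasets.

    Rows are (gene, status) pairs — a two-column TSV, or a single column of
    names using ``-U`` / ``-A`` suffixes; columns are cell barcodes; the map
    is a headerless 3-column TSV (barcode, sample, cluster).  Returns one
    single-cell ECDataset per cluster (singleton ECs with summed S/U/A
    counts) plus the number of barcodes dropped because they were absent
    from the map.
    """
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).tocsc()
    rows = pd.read_csv(rows_path, sep="\t", header=None, dtype=str)
    if rows.shape[1] >= 2:
        genes, statuses = rows[0].tolist(), rows[1].tolist()
    else:
        genes, statuses = [], []
        for name in rows[0]:
            if name.endswith("-U"):
                genes.append(name[:-2]); statuses.append("U")
            elif name.endswith("-A"):
                genes.append(name[:-2]); statuses.append("A")
            else:
                genes.append(name); statuses.append("S")
    if len(genes) != mat.shape[0]:
        raise InputError("row annotation length does not match matrix")
    for s in statuses:
        if s not in ("S", "U", "A"):
            raise InputError(f"row annotation carries invalid or missing status {s!r}")
    barcodes = pd.read_csv(cols_path, sep="\t", header=None, dtype=str)[0].tolist()
    if len(barcodes) != mat.shape[1]:
        raise InputError("column annotation length does not match matrix")

    if isinstance(barcode_cluster_map, pd.DataFrame):
        bc_map = barcode_cluster_map.copy()
        bc_map.columns = ["barcode", "sample", "cluster"][: bc_map.shape[1]]
    else:
        bc_map = pd.read_csv(barcode_cluster_map, sep="\t", header=None, dtype=str)
        bc_map.columns = ["barcode", "sample", "cluster"]
    dup = bc_map[bc_map.duplicated("barcode", keep=False)]
    if len(dup) and dup.groupby("barcode")["sample"].nunique().max() > 1:
        raise InputError("barcode collision: the same barcode is mapped to multiple samples")
    bc_map = bc_map.drop_duplicates("barcode")
    assignment = bc_map.set_index("barcode")

    gene_ids = tuple(dict.fromkeys(genes))
    fidx = FeatureIndex(gene_ids, SINGLE_CELL)
    row_feat = np.array([fidx.index_of(g) for g in genes])
    row_stat = np.array([int(SpliceStatus[s]) for s in statuses])

    dropped = 0
    # (cluster, sample) -> (F, 3) float accumulator
    acc: dict[tuple[str, str], np.ndarray] = {}
    mat = mat.tocsc()
    for j, bc in enumerate(barcodes):
        if bc not in assignment.index:
            dropped += 1
            continue
        sample, cluster = assignment.loc[bc, "sample"], assignment.loc[bc, "cluster"]
        key = (str(cluster), str(sample))
        if key not in acc:
            acc[key] = np.zeros((len(fidx), 3))
        col = mat.getcol(j)
        acc[key][row_feat[col.indices], row_stat[col.indices]] += col.data
    if dropped:
        logger.info("read_usa_mtx: dropped %d barcodes absent from the map", dropped)

    datasets: list[ECDataset] = []
    for cluster in sorted({c for c, _ in acc}):
        sample_ids = sorted(s for c, s in acc if c == cluster)
        classes = []
        for sid in sample_ids:
            table = acc[(cluster, sid)]
            ecs = [
                EquivalenceClass(((int(f), SpliceStatus(int(k))),), int(round(table[f, k])))
                for f, k in zip(*np.nonzero(table))
            ]
            classes.append(merge_classes(ecs))
        datasets.append(
            ECDataset(
                feature_index=fidx,
                sample_ids=sample_ids,
                classes=classes,
                cluster_id=cluster,
            )
        )
    return datasets, dropped


def collapse_intragene_ambiguity(dataset: ECDataset) -> ECDataset:
    """Fold same-gene S+U (or S/U with A) member pairs into a single A member.

    Single-cell convention: a read compatible with both splice versions of
    one gene is ambiguous (A) for that gene, and only multi-gene ambiguity
    is handled by latent allocation.
    """
    if dataset.mode != SINGLE_CELL:
        raise InputError("intragene ambiguity collapsing applies to single-cell data")
    new_classes = []
    for sample_classes in dataset.classes:
        ecs = []
        for ec in sample_classes:
            by_feat: dict[int, set[SpliceStatus]] = {}
            for f, s in ec.members:
                by_feat.setdefault(f, set()).add(s)
            members = []
            for f, stats in by_feat.items():
                if SpliceStatus.S in stats and SpliceStatus.U in stats:
                    members.append((f, SpliceStatus.A))
                else:
                    members.extend((f, s) for s in stats)
            ecs.append(EquivalenceClass(tuple(set(members)), ec.count))
        new_classes.append(merge_classes(ecs))
    return replace(dataset, classes=new_classes)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def equal_split_totals(dataset: ECDataset) -> np.ndarray:
    """(F, n_samples) equal-split feature totals.

    Each EC's count is divided equally among the *distinct features* in the
    class (splice statuses of one feature pooled).  This allocation is used
    for filtering and empirical-Bayes moment fits, which must not depend on
    model parameters.
    """
    totals = np.zeros((len(dataset.feature_index), dataset.n_samples))
    for i, sample_classes in enumerate(dataset.classes):
        for ec in sample_classes:
            feats = ec.features
            totals[list(feats), i] += ec.count / len(feats)
    return totals


def equal_split_status_counts(dataset: ECDataset) -> np.ndarray:
    """(n_samples, F, K) equal-split counts per (feature, status) member."""
    x = np.zeros((dataset.n_samples, len(dataset.feature_index), dataset.feature_index.n_statuses))
    for i, sample_classes in enumerate(dataset.classes):
        for ec in sample_classes:
            share = ec.count / len(ec.members)
            for f, s in ec.members:
                x[i, f, int(s)] += share
    return x


def filter_features(
    data: ECDataset | Sequence[ECDataset],
    min_count: int = 10,
):
    """Keep features with at least ``min_count`` equal-split counts in *both* groups.

    EC member sets are restricted to the kept features; classes losing all
    members are dropped, classes retaining members keep their full count.
    Returns ``(filtered, report)`` where ``report`` is a per-feature
    DataFrame of group totals and the kept flag.  For a list of per-cluster
    datasets, a list of (filtered, report) pairs is returned.
    """
    if not isinstance(data, ECDataset):
        return [filter_features(d, min_count) for d in data]
    dataset = data
    for g in GROUP_LABELS:
        if not dataset.samples_in_group(g):
            raise InputError(f"filtering requires samples in both groups; group {g} is empty")
    totals = equal_split_totals(dataset)
    group_totals = np.column_stack(
        [totals[:, dataset.samples_in_group(g)].sum(axis=1) for g in GROUP_LABELS]
    )
    kept = np.all(group_totals >= min_count, axis=1)
    report = pd.DataFrame(
        {
            "feature_id": dataset.feature_index.ids,
            "total_A": group_totals[:, 0],
            "total_B": group_totals[:, 1],
            "kept": kept,
        }
    )
    if not kept.any():
        raise InputError("no feature passes the minimum-count filter")
    if kept.all():
        return dataset, report

    old_to_new = -np.ones(len(dataset.feature_index), dtype=int)
    old_to_new[np.flatnonzero(kept)] = np.arange(int(kept.sum()))
    fi = dataset.feature_index
    new_index = FeatureIndex(
        tuple(fid for fid, k in zip(fi.ids, kept) if k),
        fi.mode,
        None if fi.eff_len_S is None else fi.eff_len_S[kept],
        None if fi.eff_len_U is None else fi.eff_len_U[kept],
    )
    new_classes = []
    for sample_classes in dataset.classes:
        ecs = []
        for ec in sample_classes:
            members = tuple(
                (int(old_to_new[f]), s) for f, s in ec.members if old_to_new[f] >= 0
            )
            if members:
                ecs.append(EquivalenceClass(members, ec.count))
        new_classes.append(merge_classes(ecs))
    filtered = ECDataset(
        feature_index=new_index,
        sample_ids=list(dataset.sample_ids),
        classes=new_classes,
        group_labels=list(dataset.group_labels),
        cluster_id=dataset.cluster_id,
    )
    return filtered, report
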