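"""Dataset assembly and leakage-free splitting.

A fusion is identified by its ordered *gene pair* (5' gene, 3' gene).  Because
fusion proteins sharing a partner gene share long stretches of sequence,
train/test independence is enforced at the gene level: the genes touched by
test fusions never occur in training fusions.  Splits therefore operate on
connected components of the gene co-occurrence graph (genes are nodes, every
fusion adds an edge between its two partners) and assign whole components to
one side, greedily largest-first with seeded tie-breaking, while balancing
class counts.

Class imbalance between the oncogenic and non-oncogenic catalogues is handled
by down-sampling the larger (NotOnco) class, preferring recurrent fusions and
matching the Onco protein-length histogram over quantile bins, so that length
alone cannot separate the classes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import ks_2samp

from .exceptions import SplitInfeasibleError, UnknownIdError

logger = logging.getLogger(__name__)

ONCO = "Onco"
NOTONCO = "NotOnco"


@dataclass
class LabeledFusion:
    """One labelled fusion protein with its gene-pair metadata."""

    fusion_id: str
    gene5: str
    gene3: str
    aa_seq: str
    label: str
    recurrent: bool = False

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("gene5 and gene3 must be non-empty")
        if self.label not in {ONCO, NOTONCO}:
            raise ValueError(f"label must be {ONCO!r} or {NOTONCO!r}, got {self.label!r}")

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def length(self) -> int:
        """Protein length in residues, not counting a terminal stop symbol."""
        return len(self.aa_seq.rstrip("*"))


@dataclass
class SplitPlan:
    """A train/test partition of fusion ids with gene-level disjointness."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int


@dataclass
class FoldPlan:
    """K bins of fusion ids; gene pairs never straddle bins."""

    bins: list[list[str]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.bins)


# -- balancing -----------------------------------------------------------------
def balance_by_downsampling(
    onco: list[LabeledFusion],
    notonco: list[LabeledFusion],
    n_length_bins: int = 10,
    seed: int = 0,
) -> list[LabeledFusion]:
    """Down-sample the NotOnco class to the Onco size with length matching.

    All Onco fusions are kept.  NotOnco fusions whose gene pair also occurs in
    the Onco class are dropped first.  The remainder are drawn per
    Onco-length-quantile bin, preferring recurrent fusions (seen in more than
    one tissue/sample) and filling up from non-recurrent ones, so both classes
    end with comparable length distributions.  A bin that cannot be filled is
    reported as a warning and left short.
    """
    if len(notonco) < len(onco):
        raise ValueError("expected the NotOnco catalogue to be at least as large as Onco")
    rng = np.random.default_rng(seed)
    onco_pairs = {f.gene_pair for f in onco}
    eligible = [f for f in notonco if f.gene_pair not in onco_pairs]
    n_conflicts = len(notonco) - len(eligible)
    if n_conflicts:
        logger.info("dropped %d NotOnco fusions whose gene pair occurs in Onco", n_conflicts)

    onco_lengths = np.array([f.length for f in onco])
    edges = np.quantile(onco_lengths, np.linspace(0, 1, n_length_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf

    def bin_of(length: int) -> int:
        return int(np.searchsorted(edges, length, side="right") - 1)

    need = np.bincount([bin_of(l) for l in onco_lengths], minlength=n_length_bins)
    by_bin: dict[int, list[LabeledFusion]] = {b: [] for b in range(n_length_bins)}
    for f in eligible:
        b = bin_of(f.length)
        by_bin[min(b, n_length_bins - 1)].append(f)

    selected: list[LabeledFusion] = []
    for b in range(n_length_bins):
        recurrent = [f for f in by_bin[b] if f.recurrent]
        other = [f for f in by_bin[b] if not f.recurrent]
        rng.shuffle(recurrent)
        rng.shuffle(other)
        pool = recurrent + other
        if len(pool) < need[b]:
            warnings.warn(
                f"length bin {b}: only {len(pool)} NotOnco candidates for {need[b]} slots"
            )
        selected.extend(pool[: need[b]])
    return list(onco) + selected


def length_distribution_ks(ds: list[LabeledFusion]) -> tuple[float, float]:
    """Two-sample KS statistic and p-value between the class length distributions."""
    a = [f.length for f in ds if f.label == ONCO]
    b = [f.length for f in ds if f.label == NOTONCO]
    res = ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# -- component machinery -------------------------------------------------------
def _components(groups: np.ndarray) -> np.ndarray:
    """Connected-component id per fusion from its (gene5, gene3) pair."""
    g = nx.Graph()
    for g5, g3 in groups:
        g.add_edge(("g", g5), ("g", g3))
    comp_of_gene: dict = {}
    for cid, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of_gene[node] = cid
    return np.array([comp_of_gene[("g", g5)] for g5, g3 in groups])


def _greedy_component_assignment(
    comp_ids: np.ndarray,
    y01: np.ndarray,
    n_bins: int,
    targets: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign whole components to bins, largest first, toward per-bin class targets.

    ``targets`` is (n_bins, 2): the desired per-class sample counts.  Each
    component goes to the bin that minimises the increment of the
    proportional potential sum_c counts[b,c]^2 / targets[b,c] — a greedy
    sum-of-squares rule that fills every bin toward its per-class target and
    keeps classes spread evenly; ties break by the seeded shuffle of the
    component order.
    """
    comps = np.unique(comp_ids)
    sizes = {c: int((comp_ids == c).sum()) for c in comps}
    order = list(comps)
    rng.shuffle(order)
    order.sort(key=lambda c: -sizes[c])

    # sizes are met within a tolerance of one component, so a component is
    # only infeasible when it cannot fit even the largest bin's rounded target
    cap = int(np.ceil(targets.sum(axis=1).max()))
    biggest = sizes[order[0]]
    if biggest > cap:
        raise SplitInfeasibleError(
            f"largest gene component holds {biggest} fusions, exceeding the "
            f"largest bin capacity {cap}"
        )
    counts = np.zeros((n_bins, 2))
    safe_targets = np.maximum(targets, 1e-9)
    assignment = np.empty(len(comp_ids), dtype=int)
    for c in order:
        mask = comp_ids == c
        add = np.array([int((y01[mask] == 0).sum()), int((y01[mask] == 1).sum())])
        # increment of sum_c counts^2 / target when adding this component
        cost = ((2 * counts * add + add**2) / safe_targets).sum(axis=1)
        best_bin = int(np.argmin(cost))
        counts[best_bin] += add
        assignment[mask] = best_bin
    return assignment


def _as_groups(groups) -> np.ndarray:
    arr = np.asarray(groups, dtype=object)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("groups must be an (n, 2) array of (gene5, gene3) names")
    return arr


class GeneDisjointSplit:
    """Single train/test split whose gene sets do not intersect.

    A cross-validation splitter in the scikit-learn style: ``split(X, y,
    groups)`` yields one ``(train_idx, test_idx)`` pair, where ``groups`` is
    an (n, 2) array of (gene5, gene3) names.  Whole connected components of
    the gene graph go to one side, so no gene — a fortiori no gene pair — is
    shared between train and test.
    """

    def __init__(self, test_fraction: float = 0.2, random_state: int | None = None):
        if not 0.0 < test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        self.test_fraction = test_fraction
        self.random_state = random_state

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return 1

    def split(self, X, y, groups):
        y = np.asarray(y)
        y01 = (y == np.unique(y)[-1]).astype(int) if y.dtype.kind in "OUS" else y.astype(int)
        groups = _as_groups(groups)
        comp_ids = _components(groups)
        rng = np.random.default_rng(self.random_state)
        n_class = np.array([int((y01 == 0).sum()), int((y01 == 1).sum())], dtype=float)
        targets = np.stack([n_class * (1 - self.test_fraction), n_class * self.test_fraction])
        assignment = _greedy_component_assignment(comp_ids, y01, 2, targets, rng)
        train_idx = np.flatnonzero(assignment == 0)
        test_idx = np.flatnonzero(assignment == 1)
        if len(test_idx) == 0 or len(train_idx) == 0:
            raise SplitInfeasibleError("a side of the split is empty")
        yield train_idx, test_idx


class GenePairKFold:
    """K-fold splitter whose bins are gene-disjoint and class-balanced.

    Bins partition the data; gene pairs (indeed genes) in one bin occur in no
    other, and per-bin Onco/NotOnco counts are balanced as far as component
    granularity allows.  ``split`` yields the usual k train/test rotations.
    """

    def __init__(self, n_splits: int = 4, random_state: int | None = None):
        if n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        self.n_splits = n_splits
        self.random_state = random_state

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def bin_assignment(self, y, groups) -> np.ndarray:
        y = np.asarray(y)
        y01 = (y == np.unique(y)[-1]).astype(int) if y.dtype.kind in "OUS" else y.astype(int)
        groups = _as_groups(groups)
        comp_ids = _components(groups)
        rng = np.random.default_rng(self.random_state)
        n_class = np.array([int((y01 == 0).sum()), int((y01 == 1).sum())], dtype=float)
        targets = np.tile(n_class / self.n_splits, (self.n_splits, 1))
        return _greedy_component_assignment(comp_ids, y01, self.n_splits, targets, rng)

    def split(self, X, y, groups):
        assignment = self.bin_assignment(y, groups)
        for b in range(self.n_splits):
            yield np.flatnonzero(assignment != b), np.flatnonzero(assignment == b)


# -- spec-level wrappers -------------------------------------------------------
def _groups_of(ds: list[LabeledFusion]) -> np.ndarray:
    return np.array([[f.gene5, f.gene3] for f in ds], dtype=object)


def _labels_of(ds: list[LabeledFusion]) -> np.ndarray:
    return np.array([f.label for f in ds])


def split_gene_disjoint(ds: list[LabeledFusion], test_fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Partition a dataset into gene-disjoint train and test sides."""
    splitter = GeneDisjointSplit(test_fraction=test_fraction, random_state=seed)
    train_idx, test_idx = next(splitter.split(ds, _labels_of(ds), _groups_of(ds)))
    return SplitPlan(
        train_ids=[ds[i].fusion_id for i in train_idx],
        test_ids=[ds[i].fusion_id for i in test_idx],
        seed=seed,
    )


def make_cv_folds(train: list[LabeledFusion], k: int = 4, seed: int = 0) -> FoldPlan:
    """Partition a training set into k gene-disjoint, class-balanced bins."""
    kf = GenePairKFold(n_splits=k, random_state=seed)
    assignment = kf.bin_assignment(_labels_of(train), _groups_of(train))
    bins = [[train[i].fusion_id for i in np.flatnonzero(assignment == b)] for b in range(k)]
    return FoldPlan(bins=bins, seed=seed)


def validate_split(plan: SplitPlan, ds: list[LabeledFusion]) -> dict:
    """Check a split plan against every disjointness and coverage invariant.

    Returns a report of booleans and counts; never mutates its inputs.
    """
    by_id = {f.fusion_id: f for f in ds}
    for fid in list(plan.train_ids) + list(plan.test_ids):
        if fid not in by_id:
            raise UnknownIdError(fid)
    train = [by_id[i] for i in plan.train_ids]
    test = [by_id[i] for i in plan.test_ids]
    genes_train = {g for f in train for g in f.gene_pair}
    genes_test = {g for f in test for g in f.gene_pair}
    shared_genes = sorted(genes_train & genes_test)
    shared_pairs = sorted({f.gene_pair for f in train} & {f.gene_pair for f in test})

    def frac_onco(part):
        return sum(f.label == ONCO for f in part) / len(part) if part else float("nan")

    ids_disjoint = not (set(plan.train_ids) & set(plan.test_ids))
    covers = set(plan.train_ids) | set(plan.test_ids) == set(by_id)
    report = {
        "n_train": len(train),
        "n_test": len(test),
        "ids_disjoint": ids_disjoint,
        "covers_dataset": covers,
        "gene_disjoint": not shared_genes,
        "shared_genes": shared_genes,
        "gene_pair_disjoint": not shared_pairs,
        "shared_gene_pairs": [list(p) for p in shared_pairs],
        "frac_onco_train": frac_onco(train),
        "frac_onco_test": frac_onco(test),
        "frac_onco_full": frac_onco(ds),
        "test_nonempty": len(test) > 0,
    }
    report["valid"] = bool(
        ids_disjoint and covers and not shared_genes and report["test_nonempty"] and len(train) > 0
    )
    return report


# -- serialization -------------------------------------------------------------
def _checksum(ids) -> str:
    h = hashlib.sha256()
    for i in sorted(ids):
        h.update(str(i).encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def save_plan(plan: SplitPlan | FoldPlan, path) -> None:
    if isinstance(plan, SplitPlan):
        payload = {
            "kind": "split",
            "seed": plan.seed,
            "train_ids": plan.train_ids,
            "test_ids": plan.test_ids,
            "checksum": _checksum(plan.train_ids + plan.test_ids),
        }
    else:
        payload = {
            "kind": "folds",
            "seed": plan.seed,
            "bins": plan.bins,
            "checksum": _checksum([i for b in plan.bins for i in b]),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_plan(path) -> SplitPlan | FoldPlan:
    with open(path) as fh:
        payload = json.load(fh)
    if payload["kind"] == "split":
        return SplitPlan(train_ids=payload["train_ids"], test_ids=payload["test_ids"], seed=payload["seed"])
    return FoldPlan(bins=payload["bins"], seed=payload["seed"])
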