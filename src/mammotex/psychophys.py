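"""Simulated psychophysics: schedules, observers, d' and RSA analyses.

Two experiment designs are modeled.  In Experiment 1 a single image is
shown per trial and the observer reports whether it is synthesized; the
design guarantees every image at least a configured number of presentations
and an exact 50-50 split between original-truth and synthesized-truth
trials.  In Experiment 2 unordered image pairs (identical pairs included)
are each shown at least the configured number of times and the observer
rates dissimilarity on a 0 (identical) to 100 (nothing comparable) scale.

Observers are generative stand-ins for human raters.  The Experiment-1
observer is a Gaussian equal-variance signal-detection model: internal
evidence ``x ~ Normal(delta * 1[synthesized], 1)`` answered "synthesized"
when ``x > c``; ``delta = c = 0`` gives the chance observer.  The
Experiment-2 rater holds a latent dissimilarity ``D`` (``d_pair`` for an
original/synthesized twin pair, ``d_class`` for same-class non-twins,
``d_diff`` otherwise, 0 on identical pairs) and reports
``clip(D + Normal(0, sigma), 0, 100)``.

Analyses: per-(subject, pair) d' with the log-linear correction
``H* = (h + 0.5) / (n + 1)`` (both task framings), RDM construction,
RDM congruity via a Spearman label-permutation test, average-linkage
hierarchical clustering, and the paired subject-level t comparison of
ratings elicited by originals vs their synthesized twins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .exceptions import (
    CoverageError,
    DegenerateDataError,
    InputError,
    ParameterError,
    StructuralError,
)
from .seeds import child_rng

__all__ = [
    "StimulusSet",
    "ObserverModel",
    "TrialSchedule",
    "ResponseTable",
    "DPrimeResult",
    "RDM",
    "LinkageTree",
    "make_schedule",
    "simulate_observer",
    "simulate_panel",
    "dprime",
    "dprime_from_rates",
    "build_rdm",
    "rdm_congruity",
    "hca",
    "paired_rating_test",
]


# ---------------------------------------------------------------------------
# stimuli and observers

@dataclass(frozen=True)
class StimulusSet:
    """k original/synthesized image pairs with class labels."""

    pairs: tuple[tuple[str, str, str], ...]  # (original id, synthesized id, class)

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        if len(self.pairs) < 1:
            raise InputError("stimulus set needs at least one pair")
        ids = [i for o, s, _ in self.pairs for i in (o, s)]
        if len(set(ids)) != len(ids):
            raise InputError("stimulus ids must be unique")

    @property
    def images(self) -> tuple[str, ...]:
        return tuple(i for o, s, _ in self.pairs for i in (o, s))

    def pair_index(self, image_id: str) -> int:
        for k, (o, s, _) in enumerate(self.pairs):
            if image_id in (o, s):
                return k
        raise InputError(f"unknown stimulus id {image_id!r}")

    def is_synth(self, image_id: str) -> bool:
        for o, s, _ in self.pairs:
            if image_id == s:
                return True
            if image_id == o:
                return False
        raise InputError(f"unknown stimulus id {image_id!r}")

    def class_of(self, image_id: str) -> str:
        for o, s, c in self.pairs:
            if image_id in (o, s):
                return c
        raise InputError(f"unknown stimulus id {image_id!r}")

    def twin(self, image_id: str) -> str:
        for o, s, _ in self.pairs:
            if image_id == o:
                return s
            if image_id == s:
                return o
        raise InputError(f"unknown stimulus id {image_id!r}")

    def latent_dissimilarity(self, a: str, b: str, d_pair: float,
                             d_class: float, d_diff: float) -> float:
        if a == b:
            return 0.0
        if self.twin(a) == b:
            return d_pair
        if self.class_of(a) == self.class_of(b):
            return d_class
        return d_diff


@dataclass(frozen=True)
class ObserverModel:
    """A simulated subject.

    kind ``chance``: responds from unbiased zero-sensitivity SDT (equivalent
    to ``sdt`` with delta = criterion = 0).  kind ``sdt``: equal-variance
    Gaussian evidence with sensitivity ``delta`` and criterion ``criterion``.
    kind ``rater``: latent-dissimilarity rater with noise ``sigma``.
    """

    kind: str = "sdt"
    delta: float = 0.0
    criterion: float = 0.0
    d_pair: float = 10.0
    d_class: float = 45.0
    d_diff: float = 80.0
    sigma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("chance", "sdt", "rater"):
            raise ParameterError(f"unknown observer kind {self.kind!r}")
        if self.sigma < 0:
            raise ParameterError("rating noise sigma must be >= 0")


# ---------------------------------------------------------------------------
# schedules

@dataclass(frozen=True)
class TrialSchedule:
    """A seeded, randomly interleaved trial order."""

    experiment: int
    trials: pd.DataFrame  # columns: trial, stim_a, stim_b (exp2), truth_synth (exp1)
    stimuli: StimulusSet
    min_presentations: int
    seed: int


def make_schedule(stimuli: StimulusSet, min_presentations: int,
                  experiment: int, seed: int = 0) -> TrialSchedule:
    """Build the trial order for one experiment.

    Experiment 1 presents every image exactly ``min_presentations`` times;
    since each pair contributes one original and one synthesized image the
    synthesized-truth fraction is exactly one half by construction.
    Experiment 2 enumerates unordered image pairs, identical pairs
    included, each exactly ``min_presentations`` times.  Orders are seeded
    uniform shuffles.
    """
    if min_presentations < 1:
        raise ParameterError("min_presentations must be >= 1")
    if experiment not in (1, 2):
        raise ParameterError("experiment must be 1 or 2")
    rng = child_rng(seed, experiment)
    if experiment == 1:
        rows = [
            {"stim_a": img, "stim_b": None, "truth_synth": stimuli.is_synth(img)}
            for img in stimuli.images
            for _ in range(min_presentations)
        ]
    else:
        rows = [
            {"stim_a": a, "stim_b": b, "truth_synth": None}
            for a, b in itertools.combinations_with_replacement(stimuli.images, 2)
            for _ in range(min_presentations)
        ]
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order])
    df.insert(0, "trial", np.arange(len(df)))
    return TrialSchedule(experiment, df, stimuli, min_presentations, seed)


# ---------------------------------------------------------------------------
# observers

@dataclass(frozen=True)
class ResponseTable:
    """Per-trial responses of one or more subjects."""

    trials: pd.DataFrame  # subject, experiment, trial, stim_a, stim_b, truth, response, rt
    experiment: int
    stimuli: StimulusSet


def simulate_observer(schedule: TrialSchedule, observer: ObserverModel,
                      subject: str = "s01") -> ResponseTable:
    """Run one simulated observer through a schedule (deterministic given seed)."""
    if schedule.experiment == 1 and observer.kind == "rater":
        raise InputError("Experiment 1 needs a chance or sdt observer")
    if schedule.experiment == 2 and observer.kind != "rater":
        raise InputError("Experiment 2 needs a rater observer")
    rng = np.random.default_rng(observer.seed)
    df = schedule.trials.copy()
    n = len(df)
    if schedule.experiment == 1:
        truth = df["truth_synth"].to_numpy(dtype=bool)
        delta = 0.0 if observer.kind == "chance" else observer.delta
        crit = 0.0 if observer.kind == "chance" else observer.criterion
        evidence = delta * truth + rng.standard_normal(n)
        df["truth"] = truth
        df["response"] = evidence > crit
    else:
        stim = schedule.stimuli
        latent = np.array([
            stim.latent_dissimilarity(a, b, observer.d_pair, observer.d_class,
                                      observer.d_diff)
            for a, b in zip(df["stim_a"], df["stim_b"])
        ])
        noise = rng.standard_normal(n) * observer.sigma
        df["truth"] = None
        df["response"] = np.clip(latent + noise, 0.0, 100.0)
    df["rt"] = np.nan  # recorded field; never analyzed
    df.insert(0, "subject", subject)
    df.insert(1, "experiment", schedule.experiment)
    return ResponseTable(df.drop(columns=["truth_synth"]), schedule.experiment,
                         schedule.stimuli)


def simulate_panel(schedule: TrialSchedule, observers) -> ResponseTable:
    """Concatenate several observers' tables (subjects s01, s02, ...)."""
    tables = [
        simulate_observer(schedule, obs, subject=f"s{k + 1:02d}")
        for k, obs in enumerate(observers)
    ]
    return ResponseTable(
        pd.concat([t.trials for t in tables], ignore_index=True),
        schedule.experiment,
        schedule.stimuli,
    )


# ---------------------------------------------------------------------------
# d-prime

@dataclass(frozen=True)
class DPrimeResult:
    """Per-(subject, pair) corrected rates and d' values."""

    table: pd.DataFrame  # subject, pair, h, f, n_s, n_o, H, F, dprime
    variant: str


def dprime_from_rates(H: float, F: float) -> float:
    """d' from already-corrected (or exact) rates: Phi^-1(H) - Phi^-1(F)."""
    return float(stats.norm.ppf(H) - stats.norm.ppf(F))


def dprime(table: ResponseTable, variant: str = "hits_vs_fa") -> DPrimeResult:
    """Per-(subject, pair) sensitivity with the log-linear correction.

    ``hits_vs_fa`` treats "synthesized" as the signal: hits are
    synthesized-truth trials answered "synthesized", false alarms are
    original-truth trials answered "synthesized".  ``tn_vs_miss`` applies
    the identical formula to the complementary framing (correct "original"
    answers vs missed synthesized images).
    """
    if variant not in ("hits_vs_fa", "tn_vs_miss"):
        raise ParameterError(f"unknown variant {variant!r}")
    if table.experiment != 1:
        raise InputError("d' analysis needs an Experiment-1 table")
    df = table.trials
    stim = table.stimuli
    pair = df["stim_a"].map(stim.pair_index)
    rows = []
    for (subject, pr), grp in df.groupby(["subject", pair], sort=True):
        truth = grp["truth"].to_numpy(dtype=bool)
        resp = grp["response"].to_numpy(dtype=bool)
        n_s = int(truth.sum())
        n_o = int((~truth).sum())
        if n_s == 0 or n_o == 0:
            raise DegenerateDataError(
                f"subject {subject!r}, pair {pr}: needs both synthesized-truth "
                f"and original-truth trials (got n_s={n_s}, n_o={n_o})"
            )
        h = int((truth & resp).sum())
        f = int((~truth & resp).sum())
        if variant == "hits_vs_fa":
            a, b = h, f
        else:  # true negatives vs misses
            a, b = n_o - f, n_s - h
            n_s, n_o = n_o, n_s  # rate denominators follow the framing
        H = (a + 0.5) / (n_s + 1.0)
        F = (b + 0.5) / (n_o + 1.0)
        rows.append({
            "subject": subject, "pair": int(pr), "h": h, "f": f,
            "n_s": int(truth.sum()), "n_o": int((~truth).sum()),
            "H": H, "F": F, "dprime": dprime_from_rates(H, F),
        })
    return DPrimeResult(pd.DataFrame(rows), variant)


# ---------------------------------------------------------------------------
# RSA

@dataclass(frozen=True)
class RDM:
    """Condition-by-condition mean dissimilarity, symmetric, zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise StructuralError("RDM matrix shape must match labels")
        object.__setattr__(self, "matrix", m)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.matrix[iu]


def build_rdm(table: ResponseTable) -> RDM:
    """Mean rating per unordered image pair, both presentation orders pooled."""
    if table.experiment != 2:
        raise InputError("RDM construction needs an Experiment-2 table")
    labels = table.stimuli.images
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for a, b, r in zip(table.trials["stim_a"], table.trials["stim_b"],
                       table.trials["response"]):
        i, j = index[a], index[b]
        sums[i, j] += r
        counts[i, j] += 1
        if i != j:
            sums[j, i] += r
            counts[j, i] += 1
    off = ~np.eye(n, dtype=bool)
    missing = [
        (labels[i], labels[j])
        for i, j in zip(*np.nonzero((counts == 0) & off))
        if i < j
    ]
    if missing:
        raise CoverageError(f"unrated image pairs: {missing}", missing=missing)
    with np.errstate(invalid="ignore"):
        mat = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(mat, 0.0)
    return RDM(labels, mat)


def rdm_congruity(a: RDM, b: RDM, n_perm: int = 1000, seed: int = 0):
    """Spearman congruity of two RDMs against a label-permutation null.

    Returns ``(rho, p)`` where rho is the Spearman rank correlation of the
    upper triangles and p is the one-sided permutation p-value
    ``(1 + #{rho_perm >= rho}) / (n_perm + 1)`` with the rows and columns
    of ``b`` permuted jointly.
    """
    if a.labels != b.labels:
        raise StructuralError("RDMs must share the same condition labels")
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    n = len(a.labels)
    iu = np.triu_indices(n, k=1)
    x = a.matrix[iu]
    rho = float(stats.spearmanr(x, b.matrix[iu]).statistic)
    # rank once; a label permutation only permutes entries of the triangle
    rng = child_rng(seed, 97)
    x_rank = stats.rankdata(x)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b.matrix[np.ix_(perm, perm)][iu]
        r = float(np.corrcoef(x_rank, stats.rankdata(bp))[0, 1])
        if r >= rho - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return rho, p


@dataclass(frozen=True)
class LinkageTree:
    """Average-linkage merge table over RDM conditions."""

    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: tuple[str, ...]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance vector (scipy ordering)."""
        return hierarchy.cophenet(self.merges)

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.merges)

        def rec(node, parent_height):
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height - 0.0:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{max(parent_height - node.dist, 0.0):g}"

        root = tree
        inner = f"({rec(root.left, root.dist)},{rec(root.right, root.dist)})"
        return inner + ";"


def hca(rdm: RDM) -> LinkageTree:
    """Agglomerative average-linkage clustering of the RDM conditions."""
    n = len(rdm.labels)
    if n < 2:
        raise StructuralError("clustering needs at least two conditions")
    condensed = rdm.matrix[np.triu_indices(n, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return LinkageTree(Z, rdm.labels)


# ---------------------------------------------------------------------------
# paired comparison

def paired_rating_test(table: ResponseTable, stimuli: StimulusSet | None = None):
    """Do originals elicit different ratings than their synthesized twins?

    Per subject: mean rating over all trials involving an original image
    minus mean rating over all trials involving its synthesized twin,
    excluding the twin-pair trials themselves from both sides.  A paired t
    statistic across subjects is returned as ``(t, p, df)`` with
    ``df = n_subjects - 1`` and a two-sided p from the t distribution.
    """
    stim = stimuli or table.stimuli
    if table.experiment != 2:
        raise InputError("paired rating comparison needs an Experiment-2 table")
    df = table.trials
    subjects = sorted(df["subject"].unique())
    if len(subjects) < 2:
        raise DegenerateDataError("paired comparison needs >= 2 subjects")
    diffs = []
    for subject in subjects:
        sub = df[df["subject"] == subject]
        orig_ratings, synth_ratings = [], []
        for o, s, _cls in stim.pairs:
            for a, b, r in zip(sub["stim_a"], sub["stim_b"], sub["response"]):
                if {a, b} == {o, s}:
                    continue  # twin-pair trials excluded from both sides
                if o in (a, b):
                    orig_ratings.append(r)
                if s in (a, b):
                    synth_ratings.append(r)
        diffs.append(np.mean(orig_ratings) - np.mean(synth_ratings))
    diffs = np.asarray(diffs)
    n = len(diffs)
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd < 1e-12:
        if abs(mean) < 1e-12:
            return 0.0, 1.0, n - 1
        raise DegenerateDataError(
            "zero-variance nonzero paired differences: t is undefined"
        )
    t = float(mean / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p, n - 1
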