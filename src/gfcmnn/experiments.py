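"""Benchmark fixtures, the medical-diagnosis demo, cross-validation, and a
synthetic IFS data generator.

The packaged medical benchmark is a small intuitionistic-fuzzy diagnosis
problem: five disease prototypes (viral fever, malaria, typhoid, stomach
problem, chest problem) described by five symptoms, four patients to be
diagnosed, and a nine-sample pool (prototypes + patients) used by a
five-round leave-the-pair-swapped cross-validation protocol.

Two label conventions coexist in the pool: the pool categories pair each
patient with the disease prototype it is exchanged against when building
cross-validation rounds, while the clinician's diagnoses are the ground
truth that predictions are scored against (Ted's swap partner is the
viral-fever prototype even though his diagnosis is malaria).
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from . import ifs
from .classify import AccuracyReport, category_similarities
from .errors import FixtureIntegrityError, InvalidSpecError
from .ifs import (
    IFSDataset,
    IFSSample,
    IFSTriple,
    ScoreMode,
    ScoreParams,
    transform_dataset,
)
from .network import NetworkShape, TrainConfig, TrainTrace, forward, train

__all__ = [
    "MedicalFixture",
    "CrossValPlan",
    "SynthSpec",
    "load_medical_fixture",
    "run_medical_example",
    "majority_medical_predictions",
    "build_crossval_rounds",
    "run_crossval",
    "crossval_over_seeds",
    "generate_synthetic",
    "DEFAULT_SHAPE",
    "DEFAULT_EXPERIMENT_CONFIG",
]

#: Network configuration of the medical experiments: 5 symptom inputs,
#: 4 layers of 5 blocks (20 fuzzy rules), 5 disease outputs, resolution 5.
DEFAULT_SHAPE = NetworkShape(n_i=5, n_j=4, n_k=5, n_o=5, n_e=5)

#: Calibrated training configuration of the experiments.  The receptive
#: fields are deliberately very wide (6-10 x the per-feature range), which
#: puts the network in a smooth, globally interpolating regime; with rules
#: that wide the activation norm approaches the rule count, so the stable
#: learning rate drops to 0.02 (the Lyapunov bound is 2/||r||^2 ~ 0.1).
#: Training stops at a summed-cost plateau of 1.5 rather than at machine
#: convergence: the classifier is read out while the fit is still smooth.
#: See docs/methods.md for the calibration rationale.
DEFAULT_EXPERIMENT_CONFIG = TrainConfig(
    eta_w=0.02,
    eta_m=0.02,
    eta_v=0.02,
    max_epochs=12000,
    cost_tol=1.5,
    init_weight_scale=0.1,
    variance_range=(6.0, 10.0),
)


@dataclass
class MedicalFixture:
    """The packaged diagnosis benchmark.

    ``diseases``: 5 prototype samples (one per category); ``patients``: the
    4 test patients labeled with the clinician's diagnosis; ``pool``: the 9
    renumbered samples (prototypes 1-5, then Ted/Al/Joe/Bob as the swap
    partners of categories 1-4).
    """

    diseases: IFSDataset
    patients: IFSDataset
    pool: IFSDataset

    def expected_label(self, pool_number: int) -> int:
        """Ground-truth category of a pool sample (1-based pool numbering).

        Prototypes keep their own category; patients carry the clinician's
        diagnosis.  Note the published pool table pairs Ted with the
        viral-fever prototype, but his diagnosis (and the expected value the
        cross-validation results are scored against) is malaria; the
        diagnosis is the ground truth used throughout.
        """
        sample = self.pool.samples[pool_number - 1]
        for p in self.patients.samples:
            if p.name == sample.name:
                return p.label
        return sample.label

    def expected_labels(self) -> np.ndarray:
        """Ground-truth categories for all pool samples, in pool order."""
        return np.array(
            [self.expected_label(n) for n in range(1, self.pool.n_samples + 1)],
            dtype=int,
        )


@dataclass
class CrossValPlan:
    """Five (train, test) splits over the 9-sample pool (1-based numbers)."""

    rounds: list[tuple[tuple[int, ...], tuple[int, ...]]]


def _load_packaged(name: str) -> IFSDataset:
    ref = resources.files("gfcmnn.data").joinpath(name)
    with resources.as_file(ref) as path:
        return ifs.read_ifs_json(path)


def load_medical_fixture() -> MedicalFixture:
    """Load the packaged diagnosis tables exactly as published.

    Two prototype triples violate the mu+nu+pi=1 constraint in the source
    tables; they are kept verbatim and loading only emits a warning.
    """
    diseases = _load_packaged("table1_diseases.json")
    patients = _load_packaged("table2_patients.json")
    pool = _load_packaged("table8_pool.json")

    def _check(cond: bool, what: str):
        if not cond:
            raise FixtureIntegrityError(f"packaged fixture corrupted: {what}")

    _check(diseases.n_samples == 5 and diseases.n_features == 5,
           "disease table must be 5 samples x 5 features")
    _check(patients.n_samples == 4 and patients.n_features == 5,
           "patient table must be 4 samples x 5 features")
    _check(pool.n_samples == 9, "pool must have 9 samples")
    _check(diseases.category_names == [
        "Viral fever", "Malaria", "Typhoid", "Stomach problem",
        "Chest problem"], "disease category names")
    # Spot checks against the published values.
    _check(diseases.samples[2].features[1].as_tuple() == (0.6, 0.1, 0.3),
           "typhoid/headache triple")
    _check(patients.samples[1].features[2].as_tuple() == (0.6, 0.1, 0.3),
           "Bob/stomach-pain triple")
    _check([s.label for s in pool.samples] == [1, 2, 3, 4, 5, 1, 2, 3, 4],
           "pool categories")

    for ds, src in ((diseases, "disease table"), (pool, "pool table")):
        ifs.warn_strict_violations(ds, source=src)
    return MedicalFixture(diseases=diseases, patients=patients, pool=pool)


def run_medical_example(
    mode: ScoreMode | str = ScoreMode.SCORE3,
    params: ScoreParams = ScoreParams(),
    shape: NetworkShape = DEFAULT_SHAPE,
    cfg: TrainConfig | None = None,
) -> tuple[np.ndarray, dict[str, int], TrainTrace]:
    """Train on the 5 disease prototypes and diagnose the 4 patients.

    Returns the 4x5 patient-by-disease similarity matrix, the predicted
    category per patient name, and the training trace.  Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or DEFAULT_EXPERIMENT_CONFIG
    fx = load_medical_fixture()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_train, y_train = transform_dataset(fx.diseases, mode, params)
        X_test, _ = transform_dataset(fx.patients, mode, params)
    net, trace = train(X_train, y_train, shape, cfg)
    sims = np.empty((fx.patients.n_samples, shape.n_o))
    preds: dict[str, int] = {}
    for i, sample in enumerate(fx.patients.samples):
        profile = category_similarities(forward(X_test[i], net), shape.n_o)
        sims[i] = profile.similarities
        preds[sample.name] = profile.predicted
    return sims, preds, trace


def majority_medical_predictions(
    mode: ScoreMode | str = ScoreMode.SCORE3,
    params: ScoreParams = ScoreParams(),
    seeds=range(10),
    shape: NetworkShape = DEFAULT_SHAPE,
    cfg: TrainConfig | None = None,
) -> dict[str, int]:
    """Per-patient majority vote of the demo predictions across seeds.

    Random initialization makes any single run's class assignment noisy; the
    majority over a seed list is the stable summary (lowest category wins a
    tied vote).
    """
    base = cfg or DEFAULT_EXPERIMENT_CONFIG
    votes: dict[str, list[int]] = {}
    for seed in seeds:
        _, preds, _ = run_medical_example(mode, params, shape,
                                          replace(base, seed=seed))
        for name, p in preds.items():
            votes.setdefault(name, []).append(p)
    return {
        name: min(
            set(vs), key=lambda c: (-vs.count(c), c)
        )
        for name, vs in votes.items()
    }


def build_crossval_rounds(fixture: MedicalFixture) -> CrossValPlan:
    """The five-round pair-swap cross-validation plan over the pool.

    Round 1 keeps the original split (train on prototypes 1-5, test on
    patients 6-9).  Each later round exchanges one diagnosis-matched
    (prototype, patient) pair, moving the patient into the training set as
    that category's exemplar and the prototype into the test set: rounds
    2-5 swap (malaria, Ted), (malaria, Al), (typhoid, Joe), and
    (stomach problem, Bob) respectively.  Two patients were diagnosed with
    malaria, so category 2 is exchanged twice; the viral-fever and
    chest-problem prototypes have no diagnosed partner and always train.
    Every round trains on 5 samples with one exemplar per category and
    tests on 4 samples.
    """
    prototypes = (1, 2, 3, 4, 5)
    patients = (6, 7, 8, 9)
    truth = fixture.expected_labels()
    rounds = [(prototypes, patients)]
    for pat in patients:
        c = truth[pat - 1]
        train_set = tuple(pat if p == c else p for p in prototypes)
        test_set = tuple(c if t == pat else t for t in patients)
        rounds.append((train_set, test_set))
    return CrossValPlan(rounds=rounds)


def run_crossval(
    mode: ScoreMode | str = ScoreMode.SCORE3,
    params: ScoreParams = ScoreParams(),
    shape: NetworkShape = DEFAULT_SHAPE,
    cfg: TrainConfig | None = None,
    fixture: MedicalFixture | None = None,
) -> tuple[list[dict], AccuracyReport]:
    """Run the five-round protocol: train afresh per round, score 20 tests.

    Returns one record per (round, test sample) with the prediction and the
    expected (ground-truth) category, plus the pooled accuracy report.
    """
    cfg = cfg or DEFAULT_EXPERIMENT_CONFIG
    fx = fixture or load_medical_fixture()
    plan = build_crossval_rounds(fx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_pool, _ = transform_dataset(fx.pool, mode, params)
    y_pool = fx.expected_labels()

    records = []
    T = N = 0
    for round_no, (train_nums, test_nums) in enumerate(plan.rounds, start=1):
        tr_idx = [n - 1 for n in train_nums]
        net, _ = train(X_pool[tr_idx], y_pool[tr_idx], shape, cfg)
        for n in test_nums:
            profile = category_similarities(forward(X_pool[n - 1], net),
                                            shape.n_o)
            expected = fx.expected_label(n)
            correct = profile.predicted == expected
            T += correct
            N += not correct
            records.append({
                "round": round_no,
                "sample": n,
                "name": fx.pool.samples[n - 1].name,
                "predicted": profile.predicted,
                "expected": expected,
            })
    return records, AccuracyReport(T=T, N=N)


def crossval_over_seeds(
    mode: ScoreMode | str = ScoreMode.SCORE3,
    params: ScoreParams = ScoreParams(),
    seeds=range(10),
    shape: NetworkShape = DEFAULT_SHAPE,
    cfg: TrainConfig | None = None,
) -> tuple[list[AccuracyReport], float, float]:
    """Cross-validation repeated over a seed list.

    Returns the per-seed accuracy reports and the medians of the accuracy
    percentage and of the correct count T across seeds.
    """
    base = cfg or DEFAULT_EXPERIMENT_CONFIG
    fx = load_medical_fixture()
    reports = []
    for seed in seeds:
        _, report = run_crossval(mode, params, shape,
                                 replace(base, seed=seed), fixture=fx)
        reports.append(report)
    med_acc = float(statistics.median(r.acc for r in reports))
    med_T = float(statistics.median(r.T for r in reports))
    return reports, med_acc, med_T


# ---------------------------------------------------------------------------
# Synthetic IFS data


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a separable synthetic IFS classification problem.

    Defaults mirror the medical benchmark's scale: 5 categories x 5
    features, category membership profiles separated by a mean gap of at
    least 0.15, small truncated-Gaussian perturbations (sd 0.03), and 4
    noisy samples per category.
    """

    n_categories: int = 5
    n_features: int = 5
    prototype_sep: float = 0.15
    noise_sd: float = 0.03
    samples_per_category: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_categories < 1 or self.n_features < 1:
            raise InvalidSpecError("counts must be >= 1")
        if self.samples_per_category < 1:
            raise InvalidSpecError("samples_per_category must be >= 1")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")
        if self.prototype_sep < 0 or self.prototype_sep > 0.9:
            raise InvalidSpecError(
                "prototype_sep must lie in [0, 0.9]: membership profiles "
                "live in the unit interval"
            )


def _triple_rows(mu_row, nu_row):
    return [IFSTriple(float(m), float(n), float(max(1.0 - m - n, 0.0)))
            for m, n in zip(mu_row, nu_row)]


def generate_synthetic(spec: SynthSpec) -> tuple[IFSDataset, IFSDataset]:
    """Draw (prototypes, noisy samples) datasets satisfying strict validation.

    Prototype membership profiles are drawn uniformly and redrawn until
    every category pair differs by at least ``prototype_sep`` in mean
    absolute membership; nonmembership takes a uniform share of the
    remaining mass and hesitation absorbs the rest.  Samples perturb their
    prototype's mu and nu with Gaussian noise truncated back into the
    admissible simplex.  Deterministic from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    C, F = spec.n_categories, spec.n_features

    mu = None
    for _ in range(500):
        cand = rng.uniform(0.05, 0.95, size=(C, F))
        ok = True
        for a in range(C):
            for b in range(a + 1, C):
                if np.mean(np.abs(cand[a] - cand[b])) < spec.prototype_sep:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            mu = cand
            break
    if mu is None:
        raise InvalidSpecError(
            f"could not place {C} membership profiles with mean separation "
            f"{spec.prototype_sep} in 500 attempts"
        )
    nu = rng.uniform(0.0, 1.0, size=(C, F)) * (1.0 - mu)

    feature_names = [f"f{i + 1}" for i in range(F)]
    category_names = [f"C{c + 1}" for c in range(C)]
    prototypes = IFSDataset(
        samples=[
            IFSSample(label=c + 1, features=_triple_rows(mu[c], nu[c]),
                      name=f"proto_C{c + 1}")
            for c in range(C)
        ],
        feature_names=feature_names,
        category_names=category_names,
    )

    samples = []
    for c in range(C):
        for s in range(spec.samples_per_category):
            m2 = np.clip(mu[c] + rng.normal(0.0, spec.noise_sd, F)
                         if spec.noise_sd > 0 else mu[c], 0.0, 1.0)
            n2 = nu[c] + (rng.normal(0.0, spec.noise_sd, F)
                          if spec.noise_sd > 0 else 0.0)
            n2 = np.clip(n2, 0.0, 1.0 - m2)
            samples.append(
                IFSSample(label=c + 1, features=_triple_rows(m2, n2),
                          name=f"C{c + 1}_s{s + 1}")
            )
    sample_ds = IFSDataset(samples=samples, feature_names=feature_names,
                           category_names=category_names)
    return prototypes, sample_ds
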