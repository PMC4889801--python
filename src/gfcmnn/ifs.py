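"""Intuitionistic fuzzy set (IFS) data model, score functions, and dataset I/O.

An intuitionistic fuzzy set assigns each element a membership degree ``mu``
and an independent nonmembership degree ``nu``; whatever mass is committed to
neither is the hesitation margin ``pi = 1 - mu - nu`` (also called the
intuitionistic fuzzy index).  A feature observation is therefore a triple
``(mu, nu, pi)`` with all three degrees in [0, 1].

Score functions scalarize a triple into a single real so that conventional
numeric classifiers can consume IFS data:

* ``score1``: ``mu - nu * pi`` — penalizes membership by hesitant
  nonmembership.
* ``score2``: ``mu + nu * pi`` — the additive counterpart, which avoids
  weakening the membership term.
* ``score3``: ``mu - nu + 1 / (alpha * pi + beta)`` — rewards a large
  membership/nonmembership gap and a small hesitation, with positive shape
  constants ``alpha`` and ``beta``.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import InvalidParamsError, InvalidTripleError, ParseError

__all__ = [
    "IFSTriple",
    "IFSSample",
    "IFSDataset",
    "ScoreParams",
    "ScoreMode",
    "hesitation_margin",
    "validate_triple",
    "validate_dataset",
    "score1",
    "score2",
    "score3",
    "transform_dataset",
    "repair_hesitation",
    "read_ifs_csv",
    "write_ifs_csv",
    "read_ifs_json",
    "write_ifs_json",
]

#: Tolerance for the strict sum constraint mu + nu + pi = 1.  Published IFS
#: tables carry one-decimal literals, so any genuine violation is gross.
SUM_TOL = 1e-9


@dataclass(frozen=True)
class IFSTriple:
    """One feature's (membership, nonmembership, hesitation) degrees."""

    mu: float
    nu: float
    pi: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mu, self.nu, self.pi)


@dataclass
class IFSSample:
    """A labeled observation: one IFS triple per feature."""

    label: int  # 1-based category index
    features: list[IFSTriple]
    name: str = ""


@dataclass
class IFSDataset:
    """Labeled samples x features of IFS triples, with category names."""

    samples: list[IFSSample]
    feature_names: list[str]
    category_names: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def subset(self, indices) -> "IFSDataset":
        """New dataset containing the given sample positions (0-based)."""
        return IFSDataset(
            samples=[self.samples[i] for i in indices],
            feature_names=list(self.feature_names),
            category_names=list(self.category_names),
        )


@dataclass(frozen=True)
class ScoreParams:
    """Shape constants of ``score3``; both must be positive."""

    alpha: float = 100.0
    beta: float = 10.0

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise InvalidParamsError(
                f"score3 constants must be positive, got alpha={self.alpha}, "
                f"beta={self.beta}"
            )


class ScoreMode(str, Enum):
    """How an IFS triple is scalarized before entering the network."""

    MEMBERSHIP = "membership"
    SCORE1 = "score1"
    SCORE2 = "score2"
    SCORE3 = "score3"


def hesitation_margin(mu: float, nu: float) -> float:
    """Hesitation degree ``pi = 1 - mu - nu`` of an IFS element.

    Raises :class:`InvalidTripleError` if ``mu + nu`` exceeds 1 beyond
    tolerance, since the hesitation degree would then be negative.
    """
    if mu < 0 or nu < 0:
        raise InvalidTripleError(f"degrees must be nonnegative, got ({mu}, {nu})")
    if mu + nu > 1 + SUM_TOL:
        raise InvalidTripleError(
            f"mu + nu = {mu + nu} exceeds 1; no admissible hesitation degree"
        )
    return max(1.0 - mu - nu, 0.0)


def validate_triple(t: IFSTriple, strict: bool = False) -> list[str]:
    """Return the list of constraint violations of a triple (empty if valid).

    Non-strict mode checks only the per-degree range constraints; strict mode
    additionally requires ``mu + nu + pi = 1`` within ``SUM_TOL``.
    """
    violations = []
    for name, value in (("mu", t.mu), ("nu", t.nu), ("pi", t.pi)):
        if not (0.0 <= value <= 1.0):
            violations.append(f"{name}-range: {name}={value} outside [0, 1]")
    if strict:
        total = t.mu + t.nu + t.pi
        if abs(total - 1.0) > SUM_TOL:
            violations.append(f"sum-violation: mu+nu+pi={total} != 1")
    return violations


def validate_dataset(ds: IFSDataset, strict: bool = False) -> list[str]:
    """Violations across a dataset, each prefixed by sample/feature location."""
    violations = []
    n_feat = ds.n_features
    for s_idx, sample in enumerate(ds.samples):
        if len(sample.features) != n_feat:
            violations.append(
                f"sample {s_idx + 1} ({sample.name!r}): has "
                f"{len(sample.features)} triples, expected {n_feat}"
            )
        if not (1 <= sample.label <= ds.n_categories):
            violations.append(
                f"sample {s_idx + 1} ({sample.name!r}): label {sample.label} "
                f"outside 1..{ds.n_categories}"
            )
        for f_idx, triple in enumerate(sample.features):
            for v in validate_triple(triple, strict=strict):
                violations.append(
                    f"sample {s_idx + 1} ({sample.name!r}), feature "
                    f"{f_idx + 1}: {v}"
                )
    return violations


def _check_ranges(t: IFSTriple) -> None:
    bad = validate_triple(t, strict=False)
    if bad:
        raise InvalidTripleError("; ".join(bad))


def score1(t: IFSTriple) -> float:
    """``mu - nu * pi``; lies in [-1, 1] for a valid triple."""
    _check_ranges(t)
    return t.mu - t.nu * t.pi


def score2(t: IFSTriple) -> float:
    """``mu + nu * pi``; lies in [0, 2] for a valid triple."""
    _check_ranges(t)
    return t.mu + t.nu * t.pi


def score3(t: IFSTriple, p: ScoreParams = ScoreParams()) -> float:
    """``mu - nu + 1 / (alpha * pi + beta)`` with positive constants."""
    _check_ranges(t)
    return t.mu - t.nu + 1.0 / (p.alpha * t.pi + p.beta)


def transform_dataset(
    ds: IFSDataset,
    mode: ScoreMode | str = ScoreMode.MEMBERSHIP,
    params: ScoreParams = ScoreParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Scalarize every triple of a dataset with the chosen score function.

    Returns ``(X, labels)`` where ``X[s, i]`` is the score of sample ``s``'s
    ``i``-th triple (row/feature order preserved) and ``labels`` are the
    1-based category indices.
    """
    try:
        mode = ScoreMode(mode)
    except ValueError:
        raise InvalidParamsError(f"unknown score mode {mode!r}") from None
    bad = validate_dataset(ds, strict=False)
    if bad:
        raise InvalidTripleError(
            "dataset fails range validation: " + "; ".join(bad[:5])
        )
    if mode is ScoreMode.MEMBERSHIP:
        fn = lambda t: t.mu
    elif mode is ScoreMode.SCORE1:
        fn = score1
    elif mode is ScoreMode.SCORE2:
        fn = score2
    else:
        fn = lambda t: score3(t, params)
    X = np.array(
        [[fn(t) for t in sample.features] for sample in ds.samples], dtype=float
    )
    X = X.reshape(ds.n_samples, ds.n_features)
    return X, ds.labels()


# ---------------------------------------------------------------------------
# Dataset I/O
#
# CSV dialect: header ``label,name,<feat>_mu,<feat>_nu,<feat>_pi,...`` with one
# sample per row, '.' decimal separator, UTF-8.  Category names are not part
# of the CSV dialect; they may be supplied by the caller, else generic names
# ``category_1..n`` are derived from the largest label.  The JSON form keeps
# everything.


def _fmt(x: float) -> str:
    return format(x, ".12g")


def read_ifs_csv(path, category_names: list[str] | None = None) -> IFSDataset:
    """Read an IFS dataset from the package CSV dialect."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file: missing header", line=1) from None
        if len(header) < 2 or header[0] != "label" or header[1] != "name":
            raise ParseError(
                "header must start with 'label,name'", line=1
            )
        feat_cols = header[2:]
        if len(feat_cols) % 3 != 0:
            raise ParseError(
                "feature columns must come in (_mu, _nu, _pi) triples", line=1
            )
        feature_names = []
        for i in range(0, len(feat_cols), 3):
            trio = feat_cols[i : i + 3]
            suffixes = [c.rsplit("_", 1)[-1] for c in trio]
            stems = {c.rsplit("_", 1)[0] for c in trio}
            if suffixes != ["mu", "nu", "pi"] or len(stems) != 1:
                raise ParseError(
                    f"malformed feature columns {trio}: expected "
                    "<feat>_mu,<feat>_nu,<feat>_pi",
                    line=1,
                )
            feature_names.append(stems.pop())

        samples = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} cells, found {len(row)}",
                    line=line_no,
                )
            try:
                label = int(row[0])
            except ValueError:
                raise ParseError(
                    f"label {row[0]!r} is not an integer", line=line_no
                ) from None
            triples = []
            for i in range(2, len(row), 3):
                try:
                    mu, nu, pi = (float(c) for c in row[i : i + 3])
                except ValueError:
                    raise ParseError(
                        f"non-numeric cell in columns {i + 1}..{i + 3}",
                        line=line_no,
                    ) from None
                triples.append(IFSTriple(mu, nu, pi))
            samples.append(IFSSample(label=label, features=triples, name=row[1]))

    if category_names is None:
        n_cat = max((s.label for s in samples), default=1)
        category_names = [f"category_{i + 1}" for i in range(n_cat)]
    return IFSDataset(
        samples=samples,
        feature_names=feature_names,
        category_names=list(category_names),
    )


def write_ifs_csv(ds: IFSDataset, path) -> None:
    """Write a dataset in canonical CSV form (decimal text, no quoting)."""
    path = Path(path)
    header = ["label", "name"]
    for f in ds.feature_names:
        header += [f"{f}_mu", f"{f}_nu", f"{f}_pi"]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for s in ds.samples:
            row = [str(s.label), s.name]
            for t in s.features:
                row += [_fmt(t.mu), _fmt(t.nu), _fmt(t.pi)]
            writer.writerow(row)


def read_ifs_json(path) -> IFSDataset:
    """Read the JSON dataset form (keeps category and sample names)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        samples = [
            IFSSample(
                label=int(s["label"]),
                features=[IFSTriple(*map(float, t)) for t in s["triples"]],
                name=s.get("name", ""),
            )
            for s in doc["samples"]
        ]
        return IFSDataset(
            samples=samples,
            feature_names=list(doc["feature_names"]),
            category_names=list(doc["category_names"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed IFS JSON document: {exc}") from exc


def write_ifs_json(ds: IFSDataset, path) -> None:
    path = Path(path)
    doc = {
        "category_names": ds.category_names,
        "feature_names": ds.feature_names,
        "samples": [
            {
                "label": s.label,
                "name": s.name,
                "triples": [list(t.as_tuple()) for t in s.features],
            }
            for s in ds.samples
        ],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def repair_hesitation(ds: IFSDataset) -> IFSDataset:
    """New dataset with every pi recomputed as 1 - mu - nu, clamped to [0,1].

    Useful for published tables whose printed hesitation degrees violate the
    sum constraint; off by default everywhere so that printed values are
    processed verbatim.
    """
    samples = [
        IFSSample(
            label=s.label,
            name=s.name,
            features=[
                IFSTriple(t.mu, t.nu, min(max(1.0 - t.mu - t.nu, 0.0), 1.0))
                for t in s.features
            ],
        )
        for s in ds.samples
    ]
    return IFSDataset(samples=samples, feature_names=list(ds.feature_names),
                      category_names=list(ds.category_names))


def warn_strict_violations(ds: IFSDataset, source: str = "dataset") -> list[str]:
    """Emit a warning for strict-constraint violations without failing.

    Published IFS tables occasionally contain triples whose degrees do not sum
    to one; these are preserved verbatim and only surfaced as warnings.
    """
    bad = [
        v for v in validate_dataset(ds, strict=True) if "sum-violation" in v
    ]
    if bad:
        warnings.warn(
            f"{source}: {len(bad)} triple(s) violate mu+nu+pi=1 and are kept "
            "as printed: " + "; ".join(bad),
            stacklevel=2,
        )
    return bad
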