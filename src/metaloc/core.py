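"""Domain types and I/O for predictor score tables and gold standards.

The atomic unit throughout the package is the *node*: a (protein,
subcellular location) pair carrying one predictor's confidence score.
A predictor's raw output for one protein is split into up to ten nodes,
one per compartment it covers.  Gold-standard location assignments are
positives-only: an unverified (protein, location) pair means "unknown",
never "absent".
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Canonical ten-compartment vocabulary, in fixed index order.
LOCATIONS: tuple[str, ...] = (
    "cytos", "ER", "extra", "Golgi", "membr",
    "mito", "nucl", "pero", "plast", "vacu",
)

LOCATION_INDEX: dict[str, int] = {code: i for i, code in enumerate(LOCATIONS)}

#: Sentinel labels some predictors emit for locations outside their scope.
#: Rows carrying them are dropped (with a logged count), never scored.
SENTINEL_LABELS = frozenset({"others", "no found"})

#: Long-form aliases accepted at parse time and mapped to canonical codes.
LOCATION_ALIASES: dict[str, str] = {
    "cytosol": "cytos",
    "cytoplasm": "cytos",
    "endoplasmic reticulum": "ER",
    "er": "ER",
    "extracellular": "extra",
    "extracellular space": "extra",
    "golgi": "Golgi",
    "golgi apparatus": "Golgi",
    "membrane": "membr",
    "plasma membrane": "membr",
    "mitochondrion": "mito",
    "mitochondria": "mito",
    "nucleus": "nucl",
    "nuclear": "nucl",
    "peroxisome": "pero",
    "plastid": "plast",
    "chloroplast": "plast",
    "vacuole": "vacu",
}


class MetalocError(Exception):
    """Base class for package errors."""


class ParseError(MetalocError):
    """Malformed input table."""


class UnknownLocationError(ParseError):
    """Location token that is neither canonical, alias, nor sentinel."""


def canonical_location(token: str) -> str:
    """Map a location token to its canonical code.

    Canonical codes are case-sensitive; aliases are matched
    case-insensitively.  Sentinel labels and unknown tokens raise.
    """
    if token in LOCATION_INDEX:
        return token
    alias = LOCATION_ALIASES.get(token.strip().lower())
    if alias is not None:
        return alias
    raise UnknownLocationError(f"unknown location token: {token!r}")


def is_sentinel(token: str) -> bool:
    return token.strip().lower() in SENTINEL_LABELS


@dataclass(frozen=True)
class Node:
    """One (protein, location) prediction unit from a single predictor."""

    protein: str
    location: str
    predictor: str
    raw_score: float
    judge: int | None = None  # 1 = gold positive, 0 = unverified

    @property
    def id(self) -> tuple[str, str]:
        return (self.protein, self.location)


@dataclass(frozen=True)
class PredictorOutput:
    """One predictor's raw scores for one protein.

    ``scores`` is a partial map location -> raw score on the predictor's
    native scale; absent keys mean the predictor emitted nothing for that
    compartment.  ``coverage`` is the set of locations the predictor is in
    principle able to score (scores' keys are always a subset of it).
    """

    predictor: str
    protein: str
    scores: Mapping[str, float]
    coverage: frozenset[str]

    def __post_init__(self):
        bad = set(self.scores) - set(LOCATIONS)
        if bad:
            raise ValueError(f"non-canonical locations in scores: {sorted(bad)}")
        if not set(self.scores) <= self.coverage:
            raise ValueError(
                f"scores outside coverage for {self.predictor}/{self.protein}"
            )
        if not self.coverage <= set(LOCATIONS):
            raise ValueError(f"coverage outside vocabulary: {sorted(self.coverage)}")
        for loc, s in self.scores.items():
            if not math.isfinite(s):
                raise ValueError(
                    f"non-finite score {s!r} at {self.predictor}/{self.protein}/{loc}"
                )


@dataclass
class GoldStandard:
    """Experimentally verified (protein, location) positives.

    ``positives`` maps protein id -> non-empty set of verified locations.
    ``split_assignment`` optionally maps protein id -> 'train' | 'test'.
    """

    positives: dict[str, set[str]]
    split_assignment: dict[str, str] | None = None

    def __post_init__(self):
        for prot, locs in self.positives.items():
            if not locs:
                raise ValueError(f"protein {prot!r} has an empty location set")
            bad = locs - set(LOCATIONS)
            if bad:
                raise ValueError(f"protein {prot!r}: unknown locations {sorted(bad)}")

    def proteins(self) -> list[str]:
        return sorted(self.positives)

    def is_positive(self, protein: str, location: str) -> bool:
        return location in self.positives.get(protein, ())

    def subset(self, proteins: Iterable[str]) -> "GoldStandard":
        keep = set(proteins)
        return GoldStandard(
            positives={p: set(v) for p, v in self.positives.items() if p in keep},
            split_assignment=None,
        )

    def split_proteins(self, which: str) -> list[str]:
        if self.split_assignment is None:
            raise MetalocError("gold standard carries no train/test split")
        return sorted(p for p, s in self.split_assignment.items() if s == which)


# ---------------------------------------------------------------------------
# Table I/O

def parse_predictor_table(path: str | Path) -> list[PredictorOutput]:
    """Read a long-format predictor score table.

    Expected TSV columns: predictor, protein, location, score.  Lines
    starting with '#' are comments; the first non-comment line must be the
    header.  Rows with sentinel location labels are dropped and counted;
    rows with non-finite scores are rejected and logged; any malformed row
    raises :class:`ParseError` with its line number.  Coverage of each
    predictor is inferred as the union of locations it scored anywhere in
    the table.
    """
    path = Path(path)
    rows: dict[tuple[str, str], dict[str, float]] = {}
    coverage: dict[str, set[str]] = {}
    dropped_sentinel = 0
    dropped_nonfinite = 0
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip().lower() for f in fields] != [
                    "predictor", "protein", "location", "score",
                ]:
                    raise ParseError(
                        f"{path}:{lineno}: bad header {fields!r}; expected "
                        "predictor/protein/location/score"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got "
                    f"{len(fields)}"
                )
            predictor, protein, loc_token, score_str = (f.strip() for f in fields)
            if not predictor or not protein:
                raise ParseError(f"{path}:{lineno}: empty predictor or protein id")
            if is_sentinel(loc_token):
                dropped_sentinel += 1
                continue
            try:
                location = canonical_location(loc_token)
            except UnknownLocationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                score = float(score_str)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: bad score {score_str!r}"
                ) from exc
            if not math.isfinite(score):
                dropped_nonfinite += 1
                logger.warning(
                    "%s:%d: non-finite score for %s/%s/%s rejected",
                    path, lineno, predictor, protein, location,
                )
                continue
            key = (predictor, protein)
            per_protein = rows.setdefault(key, {})
            if location in per_protein:
                raise ParseError(
                    f"{path}:{lineno}: duplicate row for "
                    f"(predictor={predictor}, protein={protein}, location={location})"
                )
            per_protein[location] = score
            coverage.setdefault(predictor, set()).add(location)
    if dropped_sentinel:
        logger.info(
            "%s: dropped %d rows with sentinel location labels", path, dropped_sentinel
        )
    outputs = [
        PredictorOutput(
            predictor=pred,
            protein=prot,
            scores=dict(scores),
            coverage=frozenset(coverage[pred]),
        )
        for (pred, prot), scores in sorted(rows.items())
    ]
    return outputs


def write_predictor_table(outputs: Iterable[PredictorOutput], path: str | Path) -> None:
    """Write outputs as the long-format TSV read by :func:`parse_predictor_table`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("predictor\tprotein\tlocation\tscore\n")
        for out in sorted(outputs, key=lambda o: (o.predictor, o.protein)):
            for loc in sorted(out.scores, key=LOCATION_INDEX.__getitem__):
                fh.write(f"{out.predictor}\t{out.protein}\t{loc}\t{out.scores[loc]!r}\n")


def parse_gold_table(path: str | Path) -> GoldStandard:
    """Read a gold-standard TSV with columns protein, location (positives only)."""
    path = Path(path)
    positives: dict[str, set[str]] = {}
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip().lower() for f in fields] != ["protein", "location"]:
                    raise ParseError(
                        f"{path}:{lineno}: bad header {fields!r}; expected "
                        "protein/location"
                    )
                header_seen = True
                continue
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            protein, loc_token = (f.strip() for f in fields)
            try:
                location = canonical_location(loc_token)
            except UnknownLocationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            positives.setdefault(protein, set()).add(location)
    return GoldStandard(positives=positives)


def write_gold_table(gold: GoldStandard, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein\tlocation\n")
        for prot in sorted(gold.positives):
            for loc in sorted(gold.positives[prot], key=LOCATION_INDEX.__getitem__):
                fh.write(f"{prot}\t{loc}\n")


# ---------------------------------------------------------------------------
# Node operations

def split_to_nodes(output: PredictorOutput) -> list[Node]:
    """Split one predictor/protein output into per-compartment nodes.

    One node per present (location, score) entry, in canonical location
    order; locations the predictor did not score yield no node.
    """
    return [
        Node(
            protein=output.protein,
            location=loc,
            predictor=output.predictor,
            raw_score=float(output.scores[loc]),
        )
        for loc in sorted(output.scores, key=LOCATION_INDEX.__getitem__)
    ]


def label_nodes(
    nodes: Sequence[Node], gold: GoldStandard, strict: bool = True
) -> list[Node]:
    """Attach judge flags: 1 if the (protein, location) pair is a gold
    positive, else 0 (meaning unverified, not absent).

    With ``strict`` (default) every node's protein must appear in the gold
    standard; otherwise nodes for unlisted proteins are silently filtered.
    Input order is preserved.
    """
    unknown = sorted({n.protein for n in nodes} - set(gold.positives))
    if unknown and strict:
        raise MetalocError(
            f"{len(unknown)} proteins absent from the gold standard: "
            f"{unknown[:10]}{'...' if len(unknown) > 10 else ''}"
        )
    labeled = []
    for n in nodes:
        if n.protein not in gold.positives:
            continue
        labeled.append(
            replace(n, judge=1 if gold.is_positive(n.protein, n.location) else 0)
        )
    return labeled


def split_train_test(
    gold: GoldStandard,
    fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = False,
) -> GoldStandard:
    """Randomly assign proteins to train/test at the protein level.

    The test set receives ``floor(n * fraction)`` proteins overall (per
    primary-location stratum when ``stratify`` is set), so a protein's
    nodes never straddle the two sides.  Reproducible under a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    proteins = sorted(gold.positives)
    if len(proteins) < 2:
        raise MetalocError("need at least 2 proteins to split")
    rng = random.Random(seed)
    assignment: dict[str, str] = {}
    if stratify:
        strata: dict[str, list[str]] = {}
        for p in proteins:
            primary = min(gold.positives[p], key=LOCATION_INDEX.__getitem__)
            strata.setdefault(primary, []).append(p)
        for members in strata.values():
            rng.shuffle(members)
            n_test = int(len(members) * fraction)
            for i, p in enumerate(members):
                assignment[p] = "test" if i < n_test else "train"
    else:
        shuffled = proteins[:]
        rng.shuffle(shuffled)
        n_test = int(len(shuffled) * fraction)
        for i, p in enumerate(shuffled):
            assignment[p] = "test" if i < n_test else "train"
    return GoldStandard(
        positives={p: set(v) for p, v in gold.positives.items()},
        split_assignment=assignment,
    )
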