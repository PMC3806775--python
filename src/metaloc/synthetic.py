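"""Synthetic gold standards, predictor ensembles and random sequences.

The generator stands in for a curated localization database and a panel
of live sequence-based predictors.  Each synthetic predictor follows a
binormal score model: for a covered location, a gold-positive node draws
its latent score from Normal(d, 1) and any other node from Normal(0, 1),
after which the score is squashed through the logistic sigmoid onto the
predictor's native (0, 1) scale.  The separation d is set from a target
AUROC through the binormal identity

    AUROC = Phi(d / sqrt(2))   <=>   d = sqrt(2) * Phi^{-1}(AUROC),

so a profile's discriminability is exactly calibratable.  Coverage masks
emulate narrow-scope predictors (signal-peptide tools that only score
one to three compartments), a miss rate models proteins a predictor
fails to score, and an optional cross-location confusion term lets a
predictor leak signal from one compartment into another's score — the
non-linear, inter-predictor structure a rank average cannot exploit but
a downstream network can.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import LOCATIONS, GoldStandard, MetalocError, PredictorOutput
from .nn import logsig

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def d_from_auroc(auroc: float) -> float:
    """Binormal separation that yields the target AUROC."""
    if not 0.0 < auroc < 1.0:
        raise ValueError(f"target AUROC must be in (0,1), got {auroc}")
    return float(np.sqrt(2.0) * norm.ppf(auroc))


def auroc_from_d(d: float) -> float:
    return float(norm.cdf(d / np.sqrt(2.0)))


@dataclass(frozen=True)
class PredictorProfile:
    """Statistical profile of one synthetic predictor.

    ``auroc`` maps each covered location to the predictor's target AUROC
    there.  ``miss_rate`` is the probability of emitting no score for a
    covered (protein, location) pair.  ``confusions`` maps
    (emit_location, true_location) -> separation d added to the
    emit_location score when the protein is a gold positive of
    true_location: the knob for engineered cross-location leakage.
    ``dependence`` in [0, 1) is the loading on an ensemble-shared latent
    noise factor (0 = predictors conditionally independent).
    """

    name: str
    coverage: tuple[str, ...]
    auroc: Mapping[str, float]
    miss_rate: float = 0.0
    confusions: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dependence: float = 0.0

    def __post_init__(self):
        if not self.coverage:
            raise ValueError(f"{self.name}: empty coverage")
        bad = set(self.coverage) - set(LOCATIONS)
        if bad:
            raise ValueError(f"{self.name}: unknown locations {sorted(bad)}")
        if set(self.auroc) != set(self.coverage):
            raise ValueError(f"{self.name}: auroc targets must match coverage")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError(f"{self.name}: miss_rate out of [0,1)")
        if not 0.0 <= self.dependence < 1.0:
            raise ValueError(f"{self.name}: dependence out of [0,1)")

    def d(self, location: str) -> float:
        target = self.auroc[location]
        if target == 0.5:
            return 0.0
        return d_from_auroc(target)


#: Default location priors: imbalanced the way curated plant data is —
#: plastid/nucleus/mitochondrion well studied, Golgi/vacuole/peroxisome minor.
DEFAULT_PRIORS: dict[str, float] = {
    "cytos": 0.12, "ER": 0.07, "extra": 0.08, "Golgi": 0.05, "membr": 0.10,
    "mito": 0.14, "nucl": 0.16, "pero": 0.05, "plast": 0.18, "vacu": 0.05,
}


@dataclass
class EnsembleConfig:
    """Everything needed to simulate a gold standard plus an ensemble.

    Two label models are available.  The default draws one primary
    location per protein from the priors, plus an occasional second one
    — realistic, but it couples compartments (a high score elsewhere is
    evidence against this one).  Setting ``independent_label_prob`` makes
    every (protein, location) positive an independent Bernoulli draw with
    that probability, removing all cross-compartment label structure;
    proteins that draw no location are discarded (a gold standard lists
    positives only).
    """

    profiles: list[PredictorProfile]
    n_proteins: int = 2000
    priors: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    multi_label_prob: float = 0.1
    independent_label_prob: float | None = None
    seed: int = 0

    def __post_init__(self):
        names = [p.name for p in self.profiles]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise MetalocError(f"duplicate predictor names: {sorted(dupes)}")
        if self.independent_label_prob is not None:
            if not 0.0 < self.independent_label_prob < 1.0:
                raise ValueError("independent_label_prob must be in (0,1)")
            return
        if set(self.priors) != set(LOCATIONS):
            raise ValueError("priors must cover exactly the 10 locations")
        total = sum(self.priors.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"priors must sum to 1, got {total}")
        if any(v <= 0 for v in self.priors.values()):
            raise ValueError("every location needs a positive prior")


def _protein_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def generate_gold(config: EnsembleConfig) -> GoldStandard:
    """Sample a multi-label gold standard from the location priors.

    Each protein gets one primary location drawn from the priors; with
    probability ``multi_label_prob`` one extra distinct location is added
    (drawn from the renormalised priors), capping multiplicity at two.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC01D]))
    ids = _protein_ids(config.n_proteins)
    locs = list(LOCATIONS)
    if config.independent_label_prob is not None:
        flags = rng.random((config.n_proteins, len(locs))) < config.independent_label_prob
        positives = {
            prot: {locs[j] for j in np.nonzero(flags[i])[0]}
            for i, prot in enumerate(ids)
            if flags[i].any()
        }
        return GoldStandard(positives=positives)
    p = np.array([config.priors[l] for l in locs])
    primary = rng.choice(len(locs), size=config.n_proteins, p=p)
    extra_flag = rng.random(config.n_proteins) < config.multi_label_prob
    positives: dict[str, set[str]] = {}
    for i, prot in enumerate(ids):
        assigned = {locs[primary[i]]}
        if extra_flag[i]:
            q = p.copy()
            q[primary[i]] = 0.0
            q /= q.sum()
            assigned.add(locs[rng.choice(len(locs), p=q)])
        positives[prot] = assigned
    return GoldStandard(positives=positives)


def generate_predictor(
    profile: PredictorProfile,
    gold: GoldStandard,
    seed: int,
    shared_latent: Mapping[tuple[str, str], float] | None = None,
) -> list[PredictorOutput]:
    """Simulate one predictor's raw scores for every protein in the gold.

    Latent score = d * 1[positive] + confusion terms + noise, squashed
    through logsig.  Noise is standard normal; with ``dependence`` > 0 it
    mixes a shared per-node latent factor with idiosyncratic noise so the
    marginal stays Normal(0, 1).
    """
    rng = np.random.default_rng(seed)
    rho = profile.dependence
    outputs = []
    for prot in gold.proteins():
        truth = gold.positives[prot]
        scores = {}
        for loc in profile.coverage:
            if profile.miss_rate and rng.random() < profile.miss_rate:
                continue
            mean = profile.d(loc) if loc in truth else 0.0
            for (emit, true_loc), extra_d in profile.confusions.items():
                if emit == loc and true_loc in truth:
                    mean += extra_d
            eps = rng.standard_normal()
            if rho > 0 and shared_latent is not None:
                z = np.sqrt(rho) * shared_latent[(prot, loc)] + np.sqrt(1 - rho) * eps
            else:
                z = eps
            scores[loc] = float(logsig(mean + z))
        if scores:
            outputs.append(
                PredictorOutput(
                    predictor=profile.name,
                    protein=prot,
                    scores=scores,
                    coverage=frozenset(profile.coverage),
                )
            )
    return outputs


def generate_negative_outputs(
    profiles: Sequence[PredictorProfile],
    protein_ids: Sequence[str],
    seed: int,
) -> list[PredictorOutput]:
    """Predictor outputs for proteins that exist in no compartment.

    Every covered node draws from the profile's negative score
    distribution Normal(0, 1) -> logsig; this is the simulated analogue
    of feeding random sequences to the live predictor panel.
    """
    ss = np.random.SeedSequence([seed, 0x0FF])
    outputs: list[PredictorOutput] = []
    for child, profile in zip(ss.spawn(len(profiles)), profiles):
        rng = np.random.default_rng(child)
        for prot in protein_ids:
            scores = {}
            for loc in profile.coverage:
                if profile.miss_rate and rng.random() < profile.miss_rate:
                    continue
                scores[loc] = float(logsig(rng.standard_normal()))
            if scores:
                outputs.append(
                    PredictorOutput(
                        predictor=profile.name,
                        protein=prot,
                        scores=scores,
                        coverage=frozenset(profile.coverage),
                    )
                )
    return outputs


def generate_ensemble(
    config: EnsembleConfig,
) -> tuple[list[PredictorOutput], GoldStandard]:
    """Gold standard plus all predictors' outputs, bit-reproducible per seed."""
    gold = generate_gold(config)
    ss = np.random.SeedSequence([config.seed, 0xE45])
    children = ss.spawn(len(config.profiles) + 1)
    shared_latent = None
    if any(p.dependence > 0 for p in config.profiles):
        latent_rng = np.random.default_rng(children[-1])
        shared_latent = {
            (prot, loc): latent_rng.standard_normal()
            for prot in gold.proteins()
            for loc in LOCATIONS
        }
    outputs: list[PredictorOutput] = []
    for child, profile in zip(children, config.profiles):
        seed = int(child.generate_state(1)[0] % (2**31))
        outputs.extend(generate_predictor(profile, gold, seed, shared_latent))
    return outputs, gold


# ---------------------------------------------------------------------------
# Presets

def _uniform_auroc(coverage: Sequence[str], auroc: float) -> dict[str, float]:
    return {loc: auroc for loc in coverage}


ALL = LOCATIONS

#: Eleven heterogeneous profiles emulating a broad live-predictor panel:
#: five wide-coverage tools of varying quality, three narrow targeting-signal
#: tools, two single-compartment specialists and one weak generalist.  The
#: Golgi and vacuole columns are deliberately poorly served (no predictor
#: above ~0.66) while plastid and nucleus are well served.
PAPERLIKE_11: list[PredictorProfile] = [
    PredictorProfile("wide-A", ALL, dict(zip(ALL, (0.82, 0.78, 0.80, 0.62, 0.79, 0.83, 0.84, 0.72, 0.86, 0.60)))),
    PredictorProfile("wide-B", ALL, dict(zip(ALL, (0.78, 0.74, 0.77, 0.66, 0.75, 0.80, 0.81, 0.70, 0.83, 0.64)))),
    PredictorProfile("wide-C", ALL, dict(zip(ALL, (0.80, 0.76, 0.74, 0.58, 0.72, 0.81, 0.72, 0.68, 0.84, 0.62)))),
    PredictorProfile("wide-D", ALL, dict(zip(ALL, (0.72, 0.70, 0.71, 0.64, 0.70, 0.76, 0.78, 0.66, 0.78, 0.66)))),
    PredictorProfile("wide-E", ALL, dict(zip(ALL, (0.74, 0.68, 0.73, 0.60, 0.68, 0.74, 0.76, 0.71, 0.80, 0.63)))),
    PredictorProfile("target-3", ("extra", "mito", "plast"),
                     {"extra": 0.78, "mito": 0.82, "plast": 0.85}),
    PredictorProfile("signal-3", ("ER", "mito", "plast"),
                     {"ER": 0.72, "mito": 0.78, "plast": 0.82}),
    PredictorProfile("sort-2", ("mito", "plast"), {"mito": 0.77, "plast": 0.81}),
    PredictorProfile("mito-1", ("mito",), {"mito": 0.84}),
    PredictorProfile("pero-1", ("pero",), {"pero": 0.78}),
    PredictorProfile("weak-F", ALL, dict(zip(ALL, (0.68, 0.66, 0.67, 0.63, 0.69, 0.70, 0.72, 0.65, 0.73, 0.65)))),
]

#: The three best wide-coverage profiles — the small community whose vote
#: already beats any single member.
THREE_COMMUNITY: list[PredictorProfile] = PAPERLIKE_11[:3]

#: Five informative full-coverage predictors plus two pure-noise ones, for
#: exercising stepwise selection.
NOISE_SPIKED: list[PredictorProfile] = [
    PredictorProfile("info-1", ALL, _uniform_auroc(ALL, 0.80)),
    PredictorProfile("info-2", ALL, _uniform_auroc(ALL, 0.78)),
    PredictorProfile("info-3", ALL, _uniform_auroc(ALL, 0.76)),
    PredictorProfile("info-4", ALL, _uniform_auroc(ALL, 0.74)),
    PredictorProfile("info-5", ALL, _uniform_auroc(ALL, 0.72)),
    PredictorProfile("noise-1", ALL, _uniform_auroc(ALL, 0.5)),
    PredictorProfile("noise-2", ALL, _uniform_auroc(ALL, 0.5)),
]

#: Five full-coverage predictors whose scores carry no cross-location
#: structure: the regime where a rank average is already sufficient.
ADDITIVE: list[PredictorProfile] = [
    PredictorProfile("add-1", ALL, _uniform_auroc(ALL, 0.80)),
    PredictorProfile("add-2", ALL, _uniform_auroc(ALL, 0.76)),
    PredictorProfile("add-3", ALL, _uniform_auroc(ALL, 0.73)),
    PredictorProfile("add-4", ALL, _uniform_auroc(ALL, 0.70)),
    PredictorProfile("add-5", ALL, _uniform_auroc(ALL, 0.67)),
]

#: The additive panel with several members rewired so that plastid
#: positives inflate the mitochondrion score and cytosol positives inflate
#: the nucleus score (one-way leakage, as when a targeting-signal feature
#: is shared between two compartments).  The rank average is confused by
#: the leaked proteins; a network seeing the whole vote vector can explain
#: the inflation away via the cleanly predicted source compartment.
CONFOUNDED: list[PredictorProfile] = [
    replace(ADDITIVE[0], name="conf-1",
            confusions={("mito", "plast"): 3.0, ("nucl", "cytos"): 3.0}),
    replace(ADDITIVE[1], name="conf-2",
            confusions={("mito", "plast"): 3.0, ("nucl", "cytos"): 3.0}),
    replace(ADDITIVE[2], name="conf-3",
            confusions={("mito", "plast"): 3.0, ("nucl", "cytos"): 3.0}),
    replace(ADDITIVE[3], name="conf-4",
            confusions={("mito", "plast"): 3.0}),
    replace(ADDITIVE[4], name="conf-5"),
]

PRESETS: dict[str, list[PredictorProfile]] = {
    "paperlike-11": PAPERLIKE_11,
    "three-community": THREE_COMMUNITY,
    "noise-spiked": NOISE_SPIKED,
    "additive": ADDITIVE,
    "confounded": CONFOUNDED,
}


def preset_config(
    name: str,
    n_proteins: int = 2000,
    seed: int = 0,
    multi_label_prob: float = 0.1,
    priors: Mapping[str, float] | None = None,
) -> EnsembleConfig:
    """EnsembleConfig for a named preset.

    The additive/confounded pair uses independent per-location labels so
    the two ensembles differ only in cross-location score leakage.
    """
    if name not in PRESETS:
        raise MetalocError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs: dict = {}
    if name in ("additive", "confounded"):
        # independent per-location labels: the vote vector carries no
        # cross-compartment label information, so any combination gain
        # must come from engineered score structure
        kwargs["independent_label_prob"] = 0.12
        kwargs["multi_label_prob"] = 0.0
    else:
        kwargs["multi_label_prob"] = multi_label_prob
    if priors is not None:
        kwargs["priors"] = dict(priors)
    return EnsembleConfig(
        profiles=list(PRESETS[name]),
        n_proteins=n_proteins,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Random sequences

def random_protein_sequences(
    n: int,
    length_range: tuple[int, int] = (50, 300),
    seed: int = 0,
) -> list[SeqRecord]:
    """Uniform i.i.d. amino-acid sequences with uniform lengths.

    These emulate sequences that exist in no compartment and feed the
    empirical null of the meta-predictor.
    """
    lo, hi = length_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < lo <= hi:
        raise ValueError(f"bad length range {length_range}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E0]))
    records = []
    aa = np.array(list(AMINO_ACIDS))
    for i in range(1, n + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=length))
        records.append(
            SeqRecord(Seq(seq), id=f"rand{i:06d}", description="synthetic random sequence")
        )
    return records
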