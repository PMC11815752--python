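"""Seeded generators for cohort and microbiome inputs.

The study design these generators emulate: three treatment arms (control,
sulfonamides, chlortetracycline) x two sexes x 7 mice, fecal 16S samples
at T0 / T30 / T60, liver histology grades 0-3, and CD4/CD8 IHC field
counts (10 fields per animal).

Microbiome counts follow a Dirichlet-multinomial model: a sample's
composition is drawn from a Dirichlet with mean equal to the (renormalised)
target profile and a concentration moment-matched to the profile's largest
stated SD; sequencing depth is gamma-distributed around the target mean
depth (159,067 reads/sample by default).  Published group profiles whose
percentages do not sum to 100 are renormalised and serve as shape targets
only.

Every generator is a pure function of (parameters, seed): reruns are
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRecord
from .microbiota import LINEAGE_LEVELS, TaxaTable, mann_whitney_u, relative_abundance

__all__ = [
    "CompositionProfile",
    "ArmSpec",
    "CohortScenario",
    "DEFAULT_DEPTH_MEAN",
    "MALE_CONTROL_PHYLA",
    "FEMALE_CONTROL_PHYLA",
    "gen_taxa_tables",
    "gen_cohort",
    "gen_ihc_counts",
    "gen_liver_grades",
    "default_scenario",
    "mann_whitney_power",
]

logger = logging.getLogger(__name__)

#: Default sequencing depth target, reads per sample.
DEFAULT_DEPTH_MEAN = 159_067

#: Control-group phylum profiles (percent mean, SD) used as generator shape
#: targets.  The male profile sums to >100% as printed and is renormalised
#: before sampling.
MALE_CONTROL_PHYLA: dict[str, tuple[float, float]] = {
    "Bacteroidota": (47.28, 2.7),
    "Firmicutes": (48.1, 4.8),
    "Desulfobacterota": (18.82, 2.38),
}
FEMALE_CONTROL_PHYLA: dict[str, tuple[float, float]] = {
    "Bacteroidota": (42.41, 7.34),
    "Firmicutes": (38.51, 2.02),
    "Desulfobacterota": (13.24, 8.2),
}

#: Fallback Dirichlet concentration when SD targets are unsatisfiable.
DEFAULT_CONCENTRATION = 50.0


@dataclass(frozen=True)
class CompositionProfile:
    """Target composition for one group: taxon -> (mean %, SD %).

    Targets are renormalised to sum to 100 before sampling.  ``sex`` is
    carried into sample metadata.
    """

    group: str
    targets: Mapping[str, tuple[float, float]]
    depth_mean: float = DEFAULT_DEPTH_MEAN
    depth_dispersion: float = 30.0  # gamma shape; larger = tighter depths
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be > 0")
        if not self.targets:
            raise ValueError("empty target profile")
        if any(m < 0 or s < 0 for m, s in self.targets.values()):
            raise ValueError("negative target mean or SD")

    def renormalised_means(self) -> dict[str, float]:
        """Target means rescaled to proportions summing to 1."""
        total = sum(m for m, _ in self.targets.values())
        if total <= 0:
            raise ValueError("target means sum to zero")
        if abs(total - 100.0) > 1e-9:
            logger.info(
                "profile %r: target means sum to %.2f%%, renormalising", self.group, total
            )
        return {t: m / total for t, (m, _) in self.targets.items()}

    def concentration(self) -> float:
        """Dirichlet concentration moment-matched to the largest-SD taxon.

        For proportion p with concentration c, SD = sqrt(p(1-p)/(c+1)), so
        c = p(1-p)/sd² − 1.  Unsatisfiable targets (c ≤ 0) fall back to a
        default concentration with a warning.
        """
        means = self.renormalised_means()
        total = sum(m for m, _ in self.targets.values())
        best_taxon = max(self.targets, key=lambda t: self.targets[t][1])
        sd_pct = self.targets[best_taxon][1]
        if sd_pct == 0:
            return 1e6  # effectively deterministic composition
        p = means[best_taxon]
        sd = sd_pct / total  # SD on the renormalised proportion scale
        c = p * (1.0 - p) / sd**2 - 1.0
        if c <= 0:
            logger.warning(
                "profile %r: SD target %.2f%% for %s implies concentration <= 0; "
                "using default %.0f",
                self.group, sd_pct, best_taxon, DEFAULT_CONCENTRATION,
            )
            return DEFAULT_CONCENTRATION
        return c


@dataclass(frozen=True)
class ArmSpec:
    """One (group, sex) arm of the cohort scenario.

    ``engraft_prob`` maps observation day -> cumulative probability that
    an animal is engrafted by that day (monotone; enforced by running
    maximum).
    """

    group: str
    sex: str
    n: int
    engraft_prob: Mapping[int, float]
    growth_rate: float = 0.25      # per day, exponential volume growth
    volume_noise: float = 0.15     # SD of multiplicative log-normal noise
    initial_volume: float = 100.0  # mm³ at detection
    baseline_weight: float = 25.0  # g
    weight_drift: float = 0.03     # g/day
    weight_noise: float = 0.4      # g, additive

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(not 0 <= p <= 1 for p in self.engraft_prob.values()):
            raise ValueError("engraftment probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortScenario:
    arms: tuple[ArmSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))


def default_scenario(seed: int = 0) -> CohortScenario:
    """The study design: 3 groups x 2 sexes x 7 animals, with cumulative
    engraftment probabilities matching the reported rooting tables."""
    female_days = (11, 14, 17)
    male_days = (13, 16, 18)
    probs = {
        ("control", "female"): (1 / 7, 1 / 7, 1.0),
        ("chlortetracycline", "female"): (3 / 7, 5 / 7, 1.0),
        ("sulfonamides", "female"): (3 / 7, 4 / 7, 6 / 7),
        ("control", "male"): (1 / 7, 4 / 7, 4 / 7),
        ("chlortetracycline", "male"): (0.0, 3 / 7, 3 / 7),
        ("sulfonamides", "male"): (0.0, 3 / 7, 4 / 7),
    }
    arms = []
    for (group, sex), ps in probs.items():
        days = female_days if sex == "female" else male_days
        arms.append(
            ArmSpec(group=group, sex=sex, n=7, engraft_prob=dict(zip(days, ps)))
        )
    return CohortScenario(arms=tuple(arms), seed=seed)


# ---------------------------------------------------------------------------


def _default_taxonomy(taxa: Sequence[str]) -> pd.DataFrame:
    """Taxonomy where each taxon is its own label at every level (suitable
    for phylum-level profiles)."""
    return pd.DataFrame(
        {lvl: list(taxa) for lvl in LINEAGE_LEVELS}, index=list(taxa)
    )


def gen_taxa_tables(
    profiles: Sequence[CompositionProfile],
    n_samples_per_group: int,
    time_points: Sequence[str] = ("T0", "T30", "T60"),
    seed: int = 0,
    taxonomy: pd.DataFrame | None = None,
) -> TaxaTable:
    """Dirichlet-multinomial taxa table for the given group profiles.

    One animal per sample slot; each animal is sampled at every time
    point.  Depth is gamma-distributed around ``depth_mean``; composition
    per sample is Dirichlet(c x p) with p the renormalised profile means.
    Deterministic for a fixed seed.
    """
    if n_samples_per_group < 1:
        raise ValueError("n_samples_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    all_taxa: list[str] = []
    for prof in profiles:
        for t in prof.targets:
            if t not in all_taxa:
                all_taxa.append(t)

    rows = []
    meta_rows = []
    index = []
    for prof in profiles:
        means = prof.renormalised_means()
        conc = prof.concentration()
        alpha = np.array([conc * means.get(t, 0.0) for t in all_taxa])
        nonzero = alpha > 0
        for a in range(n_samples_per_group):
            animal_id = f"{prof.group}_{prof.sex}_{a + 1}"
            for tp in time_points:
                depth = max(
                    1,
                    int(
                        round(
                            rng.gamma(
                                prof.depth_dispersion,
                                prof.depth_mean / prof.depth_dispersion,
                            )
                        )
                    ),
                )
                p = np.zeros(len(all_taxa))
                if nonzero.sum() == 1:
                    p[nonzero] = 1.0
                else:
                    p[nonzero] = rng.dirichlet(alpha[nonzero])
                counts = rng.multinomial(depth, p)
                sample_id = f"{animal_id}_{tp}"
                index.append(sample_id)
                rows.append(counts)
                meta_rows.append(
                    {
                        "group": prof.group,
                        "sex": prof.sex,
                        "time_point": tp,
                        "animal_id": animal_id,
                    }
                )
    counts = pd.DataFrame(rows, index=index, columns=all_taxa)
    meta = pd.DataFrame(meta_rows, index=index)
    tax = taxonomy if taxonomy is not None else _default_taxonomy(all_taxa)
    return TaxaTable(counts=counts, taxonomy=tax, sample_meta=meta)


def gen_cohort(scenario: CohortScenario) -> list[CohortRecord]:
    """Simulate cohort records under the scenario.

    Engraftment uses one latent uniform per animal against the cumulative
    day probabilities (exact marginals, monotone by construction).
    Engrafted animals grow tumors exponentially with multiplicative
    log-normal noise; weights follow baseline + drift x day + noise.
    """
    rng = np.random.default_rng(scenario.seed)
    records = []
    for arm in scenario.arms:
        days = sorted(arm.engraft_prob)
        cum = np.maximum.accumulate([arm.engraft_prob[d] for d in days])
        for a in range(arm.n):
            u = rng.uniform()
            engrafted = {d: bool(u <= c) for d, c in zip(days, cum)}
            engraft_day = next((d for d in days if engrafted[d]), None)
            volumes = {}
            for d in days:
                if engraft_day is not None and d >= engraft_day:
                    noise = (
                        np.exp(rng.normal(0.0, arm.volume_noise))
                        if arm.volume_noise > 0
                        else 1.0
                    )
                    volumes[d] = (
                        arm.initial_volume
                        * np.exp(arm.growth_rate * (d - engraft_day))
                        * noise
                    )
                else:
                    volumes[d] = 0.0
            weights = {
                d: arm.baseline_weight
                + arm.weight_drift * d
                + (rng.normal(0.0, arm.weight_noise) if arm.weight_noise > 0 else 0.0)
                for d in [0, *days]
            }
            records.append(
                CohortRecord(
                    animal_id=f"{arm.group}_{arm.sex}_{a + 1}",
                    sex=arm.sex,
                    group=arm.group,
                    weights=weights,
                    tumor_volumes=volumes,
                    engrafted_by_day=engrafted,
                )
            )
    return records


def gen_ihc_counts(
    group_means: Mapping[str, float],
    field_sd: float,
    n_animals: int,
    n_fields: int = 10,
    seed: int = 0,
    marker: str = "CD4",
) -> pd.DataFrame:
    """Per-field IHC positive-cell counts, long format.

    Counts are rounded truncated normals around each group's target mean
    (``field_sd`` 0 gives every field exactly the rounded target, so each
    per-animal mean equals an integer target exactly).
    """
    if field_sd < 0 or n_animals < 1 or n_fields < 1:
        raise ValueError("invalid IHC generation parameters")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean in group_means.items():
        for a in range(n_animals):
            animal_id = f"{group}_{a + 1}"
            if field_sd == 0:
                counts = np.full(n_fields, max(0, round(mean)))
            else:
                counts = np.clip(
                    np.round(rng.normal(mean, field_sd, size=n_fields)), 0, None
                ).astype(int)
            rows.extend(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "marker": marker,
                    "field_index": i + 1,
                    "count": int(c),
                }
                for i, c in enumerate(counts)
            )
    return pd.DataFrame(rows)


def gen_liver_grades(
    proportions: Mapping[str, Sequence[float]],
    n: Mapping[str, int] | int,
    seed: int = 0,
) -> dict[str, dict[int, int]]:
    """Multinomial draw of histology grade counts per group.

    ``proportions`` maps group -> probabilities over grades 0..3
    (normalised internally); ``n`` is a per-group mapping or a common
    total.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[int, int]] = {}
    for group, props in proportions.items():
        p = np.asarray(props, dtype=float)
        if (p < 0).any() or p.sum() <= 0:
            raise ValueError(f"{group}: invalid grade proportions")
        p = p / p.sum()
        total = n[group] if isinstance(n, Mapping) else int(n)
        draw = rng.multinomial(total, p)
        out[group] = {g: int(c) for g, c in enumerate(draw)}
    return out


def mann_whitney_power(
    profile_a: CompositionProfile,
    profile_b: CompositionProfile,
    taxon: str,
    n_per_group: int,
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the Mann–Whitney U test for a between-group
    difference in one taxon's relative abundance, under this module's own
    generative model.  Uses one sample (single time point) per animal."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        table = gen_taxa_tables(
            [profile_a, profile_b], n_per_group, time_points=("T0",), seed=sub_seed
        )
        rel = relative_abundance(table)
        meta = table.sample_meta.loc[rel.index]
        x = rel.loc[meta["group"] == profile_a.group, taxon]
        y = rel.loc[meta["group"] == profile_b.group, taxon]
        res = mann_whitney_u(x.to_numpy(), y.to_numpy())
        rejections += res.p_value <= alpha
    return rejections / n_reps
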