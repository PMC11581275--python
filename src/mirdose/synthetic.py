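"""Synthetic cohort generator with planted, recoverable structure.

Counts are negative-binomial around library-size-scaled feature means, one
sample per animal per timepoint. Planted effects act multiplicatively on the
log2 scale of post-irradiation means, so log2 fold change is linear in dose
(Gy) or time (days) by construction and survival-discriminative features
separate survivors from decedents by a constant log2 shift. A paired
two-species mature-miRNA FASTA generator plants homologue pairs at requested
percent identities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TIMEPOINT_DAYS, StudyDesign, default_design

log = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted into a simulated cohort.

    dose_markers: (feature, slope sign, |log2 effect| per Gy)
    time_markers: (feature, slope sign, |log2 effect| per day)
    sex_markers: (feature, sex in {"M","F"}, log2 effect in that sex)
    survival_panel: (feature, log2 shift in decedents vs survivors)
    """

    dose_markers: tuple[tuple[str, int, float], ...] = ()
    time_markers: tuple[tuple[str, int, float], ...] = ()
    sex_markers: tuple[tuple[str, str, float], ...] = ()
    survival_panel: tuple[tuple[str, float], ...] = ()

    def features(self) -> set[str]:
        out = {f for f, *_ in self.dose_markers}
        out |= {f for f, *_ in self.time_markers}
        out |= {f for f, *_ in self.sex_markers}
        out |= {f for f, _ in self.survival_panel}
        return out

    def validate(self, feature_ids) -> None:
        missing = self.features() - set(feature_ids)
        if missing:
            raise ValueError(f"planted features absent from matrix: {sorted(missing)}")
        for _, _, e in self.dose_markers + self.time_markers:
            if not np.isfinite(e):
                raise ValueError("non-finite planted effect size")


def default_planted_truth() -> PlantedTruth:
    """Study-like planted structure on the first simulated features.

    Five dose markers (0.5 log2 units/Gy, mixed signs) and eleven time
    markers (0.3 log2 units/day) — effect magnitudes chosen so the per-marker
    regression F statistics land in the range reported for such markers
    (roughly F 7-80) — plus one male- and one female-specific marker and a
    three-feature survival panel (1.2 log2 units between outcome classes),
    matching the marker counts the screening stages are expected to recover.
    The survival shift (0.6 log2 units) makes each panel member an imperfect
    single classifier, so the combined panel — not any one feature — carries
    the discriminative signal, as in real prognostic-panel data.
    """
    dose = tuple(
        (f"mir-{i:04d}", s, 0.6) for i, s in zip(range(5), (-1, -1, -1, 1, -1))
    )
    time = tuple(
        (f"mir-{i:04d}", s, 0.3)
        for i, s in zip(range(5, 16), (1, 1, 1, -1, -1, -1, 1, 1, 1, 1, -1))
    )
    sex = (("mir-0016", "M", 1.0), ("mir-0017", "F", 1.0))
    surv = tuple((f"mir-{i:04d}", 0.6) for i in range(18, 21))
    return PlantedTruth(dose, time, sex, surv)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the count simulator.

    n_features: number of simulated miRNAs (study cohorts detect ~1,000-1,300).
    baseline_mean: median expected count of a feature at reference depth;
        feature means are log-normal around it (sdlog ``mean_sdlog``) so the
        matrix spans strongly- and weakly-detected miRNAs.
    dispersion: negative-binomial dispersion (var = mu + dispersion * mu^2).
        Samples are drawn independently, so this is the within-animal
        (repeated serum sampling) dispersion — the component that per-animal
        baselining cannot cancel; 0.05 corresponds to a 22% biological CV.
    library_size_range: per-sample relative depth is uniform in this range,
        scaled by its midpoint.
    """

    n_features: int = 1200
    baseline_mean: float = 50.0
    dispersion: float = 0.05
    library_size_range: tuple[float, float] = (2_000_000.0, 8_000_000.0)
    mean_sdlog: float = 1.5
    planted: PlantedTruth = field(default_factory=default_planted_truth)
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 50:
            raise ValueError("n_features must be >= 50")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid library_size_range")


def _feature_ids(n: int) -> list[str]:
    return [f"mir-{i:04d}" for i in range(n)]


def simulate_cohort(
    config: SimulationConfig, design: StudyDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate one cohort: counts (features x samples), metadata, truth.

    One sample per animal per timepoint. Metadata columns: sample_id,
    animal_id, dose_gy, timepoint, sex, survived. Survivor labels are drawn
    so every dose group has exactly its designed survivor count.
    """
    design = design or default_design()
    design.validate()
    config.validate()
    features = _feature_ids(config.n_features)
    config.planted.validate(features)

    rng = np.random.default_rng(config.seed)

    # Animal roster.
    rows = []
    idx = 0
    for g in design.groups:
        sexes = ["M"] * g.n_male + ["F"] * g.n_female
        survived = np.zeros(g.n_animals, bool)
        survived[rng.choice(g.n_animals, size=g.n_survived, replace=False)] = True
        for a in range(g.n_animals):
            idx += 1
            rows.append((f"A{idx:02d}", g.dose_gy, sexes[a], bool(survived[a])))
    animals = pd.DataFrame(rows, columns=["animal_id", "dose_gy", "sex", "survived"])

    meta = animals.loc[animals.index.repeat(len(design.timepoints))].reset_index(
        drop=True
    )
    meta["timepoint"] = list(design.timepoints) * len(animals)
    meta["sample_id"] = meta["animal_id"] + "_" + meta["timepoint"]
    meta = meta[["sample_id", "animal_id", "dose_gy", "timepoint", "sex", "survived"]]

    # Baseline feature means (log-normal; heavy right tail). Planted markers
    # are floored at the median scale: a usable biomarker is by necessity a
    # well-detected feature.
    base = rng.lognormal(np.log(config.baseline_mean), config.mean_sdlog, len(features))
    planted_idx = [i for i, f in enumerate(features) if f in config.planted.features()]
    base[planted_idx] = np.maximum(base[planted_idx], config.baseline_mean)

    # Per-sample relative depth.
    lo, hi = config.library_size_range
    depth = rng.uniform(lo, hi, len(meta)) / ((lo + hi) / 2.0)

    # Log2 effect matrix, non-zero only for post-irradiation samples.
    shift = np.zeros((len(features), len(meta)))
    fpos = {f: i for i, f in enumerate(features)}
    post = (meta["timepoint"] != "pre").to_numpy()
    dose = meta["dose_gy"].to_numpy()
    days = meta["timepoint"].map(TIMEPOINT_DAYS).fillna(0.0).to_numpy()
    male = (meta["sex"] == "M").to_numpy()
    died = (~meta["survived"]).to_numpy()
    for f, sign, eff in config.planted.dose_markers:
        shift[fpos[f]] += np.where(post, sign * eff * dose, 0.0)
    for f, sign, eff in config.planted.time_markers:
        shift[fpos[f]] += np.where(post, sign * eff * days, 0.0)
    for f, sx, eff in config.planted.sex_markers:
        sel = male if sx == "M" else ~male
        shift[fpos[f]] += np.where(post & sel, eff, 0.0)
    for f, eff in config.planted.survival_panel:
        shift[fpos[f]] += np.where(post & died, eff, 0.0)

    mu = base[:, None] * depth[None, :] * np.exp2(shift)
    size = 1.0 / config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=features, columns=meta["sample_id"].to_numpy()
    )
    counts_df.index.name = "feature_id"
    return counts_df, meta, config.planted


@dataclass(frozen=True)
class HomologyMap:
    """Requested cross-species homologue pairs: (id_a, id_b, percent identity)."""

    pairs: tuple[tuple[str, str, float], ...] = ()

    def validate(self) -> None:
        for a, b, pct in self.pairs:
            if not 0 <= pct <= 100:
                raise ValueError(f"identity {pct} for ({a},{b}) outside [0,100]")


def _random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list(RNA_ALPHABET), size=length))


def simulate_mirna_fasta(
    homology: HomologyMap,
    path_a,
    path_b,
    seed: int = 0,
    length_range: tuple[int, int] = (18, 30),
    n_decoys_a: int = 0,
    n_decoys_b: int = 0,
) -> dict[tuple[str, str], float]:
    """Write paired mature-miRNA FASTA files for two species.

    For each homologue pair the species-B sequence is the species-A sequence
    with ``k`` substitutions at distinct random positions, where ``k`` rounds
    the requested identity to the nearest achievable on that length; the
    realized identity of each pair is returned. Identities not exactly
    achievable are rounded and reported with a warning. Unpaired decoy
    sequences can be added to either file.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    homology.validate()
    lo, hi = length_range
    if not 18 <= lo <= hi <= 30:
        raise ValueError("mature miRNA lengths must lie in 18-30 nt")
    rng = np.random.default_rng(seed)

    recs_a, recs_b, realized = [], [], {}
    for id_a, id_b, pct in homology.pairs:
        length = int(rng.integers(lo, hi + 1))
        seq_a = _random_rna(rng, length)
        k = int(round(length * (1.0 - pct / 100.0)))
        got = 100.0 * (length - k) / length
        if abs(got - pct) > 1e-9:
            warnings.warn(
                f"identity {pct:.2f}% not achievable on {length} nt for "
                f"({id_a},{id_b}); rounded to {got:.2f}%",
                stacklevel=2,
            )
        seq_b = list(seq_a)
        for pos in rng.choice(length, size=k, replace=False):
            seq_b[pos] = rng.choice([c for c in RNA_ALPHABET if c != seq_a[pos]])
        recs_a.append(SeqRecord(Seq(seq_a), id=id_a, description=""))
        recs_b.append(SeqRecord(Seq("".join(seq_b)), id=id_b, description=""))
        realized[(id_a, id_b)] = got

    for n, recs, tag in ((n_decoys_a, recs_a, "a"), (n_decoys_b, recs_b, "b")):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            recs.append(
                SeqRecord(
                    Seq(_random_rna(rng, length)), id=f"decoy-{tag}-{i:03d}",
                    description="",
                )
            )

    SeqIO.write(recs_a, str(path_a), "fasta")
    SeqIO.write(recs_b, str(path_b), "fasta")
    return realized
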