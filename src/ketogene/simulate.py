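"""Synthetic dairy-cow cohort generator.

The study cohort this package analyzes (977 analyzable Polish
Holstein-Friesian test-day records, osteopontin c.495C>T genotypes, blood
BHB phenotypes) was never deposited, so every downstream stage is exercised
on synthetic cohorts whose statistical structure matches what the analysis
assumes:

* genotypes drawn i.i.d. under Hardy-Weinberg proportions at a configurable
  C-allele frequency (default: the direct-count estimate 1305/1954 from the
  observed genotype counts);
* subclinical ketosis (SCK) assigned per animal with a genotype-dependent
  penetrance (defaults: CC 25/410, CT 23/485, TT 1/82 — the observed
  per-genotype case fractions);
* blood BHB consistent with the >= 1.0 mmol/L case definition by
  construction: healthy animals draw from a normal distribution truncated
  to (0, threshold), SCK animals from threshold + an exponential excess;
* a small i.i.d. contamination process (default rate 2/979) that voids the
  ketosis test of affected records, mirroring the two records the field
  study lost to contamination.

A single integer seed drives everything; per-stage generators are spawned
deterministically from it, so a fixed seed yields a bit-identical cohort
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import EmptyInputError, ParameterError
from .rflp import MNLI, EnzymeDef, PrimerPair, revcomp

GENOTYPES = ("CC", "CT", "TT")

#: Column order of the cohort CSV written/read by this package.
COHORT_COLUMNS = [
    "animal_id",
    "lactation_group",
    "bhb_mmol_l",
    "milk_kg",
    "fat_pct",
    "protein_pct",
    "lactose_pct",
    "dry_matter_pct",
    "urea_mg_l",
    "scc_k_per_ml",
    "contaminated",
    "genotype",
    "sck_truth",
]

#: Primer pair of the osteopontin exon-1 assay (5'->3').
ASSAY_PRIMERS = PrimerPair(
    forward="GTGTGTGCCTGTGTTTGTTC",
    reverse="GAGAAGAGTCCAGTCCCCTG",
)

# Lactation-1-style milk-variable moments used for all groups: (mean, sd).
_MILK_MOMENTS = {
    "milk_kg": (24.84, 9.53),
    "fat_pct": (4.08, 0.86),
    "protein_pct": (3.60, 0.35),
    "lactose_pct": (4.91, 0.19),
    "dry_matter_pct": (13.33, 1.53),
    "urea_mg_l": (235.82, 66.04),
}
_SCC_MEAN, _SCC_SD = 172.46, 394.66  # heavy-tailed; modeled log-normal


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults emulate the study conditions: 979 records, C-allele frequency
    1305/1954, per-genotype SCK penetrances 25/410 (CC), 23/485 (CT),
    1/82 (TT), healthy BHB 0.47 +/- 0.24 mmol/L, contamination 2/979, and
    lactation-group sizes proportional to 326/291/197/87/50/28.
    """

    n_animals: int = 979
    allele_freq_C: float = 1305 / 1954
    penetrance: Mapping[str, float] = field(
        default_factory=lambda: {"CC": 25 / 410, "CT": 23 / 485, "TT": 1 / 82}
    )
    bhb_healthy_mean: float = 0.47
    bhb_healthy_sd: float = 0.24
    bhb_sck_min: float = 1.0
    bhb_sck_scale: float = 0.4
    contamination_rate: float = 2 / 979
    lactation_weights: Sequence[float] = (
        326 / 979,
        291 / 979,
        197 / 979,
        87 / 979,
        50 / 979,
        28 / 979,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        probs = [self.allele_freq_C, self.contamination_rate, *self.penetrance.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ParameterError("all probabilities must lie in [0, 1]")
        if set(self.penetrance) != set(GENOTYPES):
            raise ParameterError("penetrance must have exactly the keys CC, CT, TT")
        if self.bhb_healthy_sd <= 0:
            raise ParameterError("bhb_healthy_sd must be > 0")
        if self.bhb_sck_min <= 0 or self.bhb_sck_scale <= 0:
            raise ParameterError("bhb_sck_min and bhb_sck_scale must be > 0")
        w = np.asarray(self.lactation_weights, dtype=float)
        if w.size != 6 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError("lactation_weights must be 6 nonnegative weights summing to 1")
        object.__setattr__(self, "lactation_weights", tuple(float(x) for x in w))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "n_animals": self.n_animals,
            "allele_freq_C": self.allele_freq_C,
            "penetrance": dict(self.penetrance),
            "bhb_healthy_mean": self.bhb_healthy_mean,
            "bhb_healthy_sd": self.bhb_healthy_sd,
            "bhb_sck_min": self.bhb_sck_min,
            "bhb_sck_scale": self.bhb_sck_scale,
            "contamination_rate": self.contamination_rate,
            "lactation_weights": list(self.lactation_weights),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: the record table, the latent truth, the config."""

    records: pd.DataFrame
    truth: pd.DataFrame  # animal_id, genotype, sck_truth
    config_echo: SimulationConfig

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _spawn(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


def hwe_proportions(p_C: float) -> np.ndarray:
    """Hardy-Weinberg genotype proportions (CC, CT, TT) at C frequency p."""
    q = 1.0 - p_C
    return np.array([p_C * p_C, 2.0 * p_C * q, q * q])


def draw_genotypes(n: int, p_C: float, rng_seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. Hardy-Weinberg genotypes at C-allele frequency ``p_C``."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0.0 <= p_C <= 1.0:
        raise ParameterError("p_C must lie in [0, 1]")
    rng = _spawn(rng_seed, 0)
    return rng.choice(GENOTYPES, size=n, p=hwe_proportions(p_C))


def draw_phenotypes(genotypes: Sequence[str], cfg: SimulationConfig) -> SyntheticCohort:
    """Attach phenotypes to ``genotypes`` under the configured generative model.

    Each animal is SCK with probability ``penetrance[genotype]``. SCK animals
    get BHB = ``bhb_sck_min`` + Exponential(scale=``bhb_sck_scale``); healthy
    animals draw from Normal(``bhb_healthy_mean``, ``bhb_healthy_sd``)
    truncated to (0, ``bhb_sck_min``), so labels and BHB are coherent with
    the diagnostic threshold by construction. Contaminated records lose their
    BHB measurement (set missing).
    """
    genotypes = np.asarray(genotypes, dtype=object)
    n = genotypes.size
    if n == 0:
        raise EmptyInputError("genotypes must be nonempty")

    rng_sck = _spawn(cfg.seed, 1)
    rng_bhb = _spawn(cfg.seed, 2)
    rng_contam = _spawn(cfg.seed, 3)
    rng_lact = _spawn(cfg.seed, 4)
    rng_milk = _spawn(cfg.seed, 5)

    pen = np.array([cfg.penetrance[g] for g in genotypes])
    sck = rng_sck.random(n) < pen

    # healthy: truncated normal on (0, threshold); SCK: shifted exponential
    a = (0.0 - cfg.bhb_healthy_mean) / cfg.bhb_healthy_sd
    b = (cfg.bhb_sck_min - cfg.bhb_healthy_mean) / cfg.bhb_healthy_sd
    bhb = np.empty(n)
    n_healthy = int((~sck).sum())
    bhb[~sck] = stats.truncnorm.rvs(
        a, b, loc=cfg.bhb_healthy_mean, scale=cfg.bhb_healthy_sd,
        size=n_healthy, random_state=rng_bhb,
    )
    bhb[sck] = cfg.bhb_sck_min + rng_bhb.exponential(cfg.bhb_sck_scale, size=int(sck.sum()))

    contaminated = rng_contam.random(n) < cfg.contamination_rate
    bhb = np.where(contaminated, np.nan, bhb)

    lactation = rng_lact.choice(np.arange(1, 7), size=n, p=cfg.lactation_weights)

    milk = {}
    for col, (mean, sd) in _MILK_MOMENTS.items():
        milk[col] = np.clip(rng_milk.normal(mean, sd, size=n), 0.01, None).round(2)
    sigma2 = np.log1p((_SCC_SD / _SCC_MEAN) ** 2)
    mu = np.log(_SCC_MEAN) - sigma2 / 2.0
    milk["scc_k_per_ml"] = rng_milk.lognormal(mu, np.sqrt(sigma2), size=n).round(1)

    records = pd.DataFrame(
        {
            "animal_id": [f"COW{i:06d}" for i in range(1, n + 1)],
            "lactation_group": lactation,
            "bhb_mmol_l": np.round(bhb, 4),
            **{c: milk[c] for c in COHORT_COLUMNS[3:10]},
            "contaminated": contaminated,
            "genotype": genotypes,
            "sck_truth": sck.astype(int),
        }
    )[COHORT_COLUMNS]
    truth = records[["animal_id", "genotype", "sck_truth"]].copy()
    return SyntheticCohort(records=records, truth=truth, config_echo=cfg)


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Full generator: Hardy-Weinberg genotypes, then phenotypes."""
    genotypes = draw_genotypes(cfg.n_animals, cfg.allele_freq_C, cfg.seed)
    return draw_phenotypes(genotypes, cfg)


# --------------------------------------------------------------------------
# Synthetic reference sequence for the in-silico assay
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReferenceAssay:
    """A synthetic template pair for the PCR-RFLP assay, with ground truth.

    The two templates differ only at the SNP offset: the T allele completes
    a CCTC MnlI site that the C allele lacks, so their digest ladders
    differ by construction. ``expected_ladders`` records, per allele, the
    fragment lengths an independent scan of the amplicon predicts.
    """

    template_C: str
    template_T: str
    snp_offset: int  # 0-based offset of the SNP in either template
    amplicon_snp_offset: int  # offset of the SNP within the amplicon
    primers: PrimerPair
    enzyme: EnzymeDef
    expected_ladders: Mapping[str, tuple[int, ...]]

    def template(self, allele: str) -> str:
        if allele not in ("C", "T"):
            raise ParameterError("allele must be 'C' or 'T'")
        return self.template_C if allele == "C" else self.template_T

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.template_C), id="allele_C", description="synthetic template, C allele"),
            SeqRecord(Seq(self.template_T), id="allele_T", description="synthetic template, T allele"),
        ]
        seqio_write(records, path, "fasta")


def _naive_ladder(amplicon: str, enzyme: EnzymeDef) -> tuple[int, ...]:
    # position-by-position scan, kept independent of rflp.digest on purpose
    site, rc_site = enzyme.recognition, revcomp(enzyme.recognition)
    k = len(site)
    cuts = set()
    for i in range(len(amplicon) - k + 1):
        window = amplicon[i : i + k]
        if window == site:
            cuts.add(i + k + enzyme.cut_offset_top)
        if window == rc_site:
            cuts.add(i - enzyme.cut_offset_top)
    cuts = sorted(c for c in cuts if 0 < c < len(amplicon))
    bounds = [0, *cuts, len(amplicon)]
    return tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))


def synthesize_reference(
    seed: int,
    primers: PrimerPair = ASSAY_PRIMERS,
    enzyme: EnzymeDef = MNLI,
    flank: int = 60,
    spacer: int = 40,
) -> ReferenceAssay:
    """Build a synthetic template pair carrying the C/T SNP inside the amplicon.

    Layout (top strand): random flank | forward primer | spacer |
    CC[C/T]C SNP context | spacer | revcomp(reverse primer) | random flank.
    The T allele completes the enzyme's CCTC recognition site. Random parts
    are redrawn until the forward primer and the reverse-primer complement
    each occur exactly once on the top strand of both allele templates and
    the two digest ladders differ; a fixed seed is fully deterministic.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E0]))
    fwd = primers.forward
    rev_site = revcomp(primers.reverse)
    site = enzyme.recognition  # CCTC: SNP sits at the position of the T

    for _ in range(1000):
        left = "".join(rng.choice(_BASES, size=flank))
        right = "".join(rng.choice(_BASES, size=flank))
        spacer1 = "".join(rng.choice(_BASES, size=spacer))
        spacer2 = "".join(rng.choice(_BASES, size=spacer))
        context_pre, context_post = site[:2], site[3:]  # "CC" + snp + "C"
        core = {
            allele: spacer1 + context_pre + allele + context_post + spacer2
            for allele in ("C", "T")
        }
        templates = {a: left + fwd + core[a] + rev_site + right for a in ("C", "T")}
        snp_offset = len(left) + len(fwd) + len(spacer1) + 2
        amp_snp_offset = len(fwd) + len(spacer1) + 2

        ok = all(
            t.count(fwd) == 1 and t.count(rev_site) == 1 for t in templates.values()
        )
        if not ok:
            continue
        amplicons = {a: fwd + core[a] + rev_site for a in ("C", "T")}
        ladders = {a: _naive_ladder(amplicons[a], enzyme) for a in ("C", "T")}
        if ladders["C"] == ladders["T"]:
            continue
        return ReferenceAssay(
            template_C=templates["C"],
            template_T=templates["T"],
            snp_offset=snp_offset,
            amplicon_snp_offset=amp_snp_offset,
            primers=primers,
            enzyme=enzyme,
            expected_ladders={a: ladders[a] for a in ("C", "T")},
        )
    raise RuntimeError("could not synthesize a valid reference in 1000 attempts")
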