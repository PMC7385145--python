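"""Synthetic genotype / phenotype / CDS generators with known ground truth.

The generator emulates the statistical structure of an elite inbred wheat
variety panel: fully homozygous lines (dosages 0/2), block-wise linkage
disequilibrium from a small founder-haplotype pool, weak continuous
population structure (Balding–Nichols beta-divergent subpopulation allele
frequencies at small Fst), additive quantitative trait loci of
small-to-medium effect with optional pairwise epistasis, and
multi-environment phenotypes generated under the two-way model

    y_ij = mu + G_i + E_j + e_ij

with residual variance solved so the entry-mean (plot-level) heritability
H^2 = Var(G) / (Var(G) + Var(e)/nE) hits a requested target. Every draw is a
pure function of the configuration seed, and a ``SimTruth`` ledger records
QTL positions, effects and the realized variance ratio so downstream stages
can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "TraitConfig",
    "SimTruth",
    "CdsTruth",
    "ConfigurationError",
    "InfeasibleTraitError",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_cds_alignment",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


class InfeasibleTraitError(ValueError):
    """Raised when the requested heritability cannot be realized."""


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Genotype-panel generator settings.

    Defaults mirror the study conditions this package targets: a panel of
    372 inbred varieties scored at 26,694 quality SNP markers on 21
    chromosomes, with two weakly diverged subpopulations (small ``fst``) so
    that the leading principal components explain only a small share of the
    marker variance.
    """

    n_lines: int = 372
    n_markers: int = 26694
    n_chromosomes: int = 21
    map_length_cM: float = 150.0
    block_size: int = 20
    n_subpops: int = 2
    fst: float = 0.05
    maf_min: float = 0.05
    n_founders: int = 8
    mosaic_noise: float = 0.02
    het_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ConfigurationError("n_lines must be >= 2")
        if self.n_markers < 1:
            raise ConfigurationError("n_markers must be >= 1")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.map_length_cM <= 0:
            raise ConfigurationError("map_length_cM must be positive")
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")
        if self.n_subpops < 1:
            raise ConfigurationError("n_subpops must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigurationError("fst must lie in [0, 1)")
        if not 0.0 < self.maf_min <= 0.5:
            raise ConfigurationError("maf_min must lie in (0, 0.5]")
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        for name in ("mosaic_noise", "het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass
class TraitConfig:
    """Trait-architecture settings for :func:`simulate_trait`.

    ``effect_distribution`` is one of ``"gaussian"`` (standard normal
    additive effects), ``"equal"`` (all effects 1) or ``"geometric:<a>"``
    (k-th QTL effect a^k, a few large loci dominating — the architecture of
    a hardness-like trait controlled by one major locus).
    """

    n_qtl: int = 50
    effect_distribution: str = "gaussian"
    h2_target: float = 0.90
    n_environments: int = 6
    env_variance: float = 1.0
    mu: float = 50.0
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    trait_name: str = "sim_trait"
    seed: int = 0

    def validate(self) -> None:
        if self.n_qtl < 0:
            raise ConfigurationError("n_qtl must be >= 0")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ConfigurationError("h2_target must lie in [0, 1]")
        if self.n_environments < 1:
            raise ConfigurationError("n_environments must be >= 1")
        if self.env_variance < 0:
            raise ConfigurationError("env_variance must be >= 0")
        for i, j, _ in self.epistatic_pairs:
            if not (0 <= i < self.n_qtl and 0 <= j < self.n_qtl):
                raise ConfigurationError(
                    f"epistatic pair ({i},{j}) indexes undeclared QTL (n_qtl={self.n_qtl})"
                )


@dataclass
class SimTruth:
    """Ground-truth ledger of a simulated trait."""

    qtl_markers: list[str]
    qtl_effects: np.ndarray
    epistatic_effects: list[tuple[str, str, float]]
    true_genetic_values: pd.Series
    realized_h2: float
    sigma2_e: float
    h2_target: float

    def qtl_variance_shares(self, geno: GenotypeMatrix) -> pd.Series:
        """Per-QTL share (%) of the simulated genetic variance.

        Computed marker by marker as Var(w_q * a_q) / Var(g) * 100; with
        epistasis or LD between QTL the shares need not sum to 100.
        """
        var_g = float(np.var(self.true_genetic_values.to_numpy(), ddof=1))
        shares = {}
        for m, a in zip(self.qtl_markers, self.qtl_effects):
            w = geno.dosages[:, geno.marker_ids.index(m)]
            shares[m] = float(np.var(w * a, ddof=1) / var_g * 100.0)
        return pd.Series(shares, name="variance_share_pct")


@dataclass
class CdsTruth:
    """Mutation ledger of a simulated CDS alignment."""

    mutations: pd.DataFrame  # site, codon_index, ref_base, alt_base, synonymous, carriers
    n_haplotypes: int

    @property
    def n_synonymous(self) -> int:
        return int(self.mutations["synonymous"].sum()) if len(self.mutations) else 0

    @property
    def n_nonsynonymous(self) -> int:
        return int((~self.mutations["synonymous"]).sum()) if len(self.mutations) else 0


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _block_sizes(n_markers: int, mean_size: int, rng: np.random.Generator) -> list[int]:
    sizes: list[int] = []
    total = 0
    while total < n_markers:
        s = int(rng.poisson(max(mean_size - 1, 0))) + 1
        s = min(s, n_markers - total)
        sizes.append(s)
        total += s
    return sizes


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate an inbred-panel dosage matrix with block LD and weak structure.

    Subpopulation allele frequencies follow the Balding–Nichols model:
    ancestral frequency p ~ U(maf_min, 1 - maf_min) per marker, subpopulation
    frequency q_s ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (q_s = p when F = 0). Within
    each LD block every subpopulation carries a small pool of founder
    haplotypes drawn from its q_s; each line copies one founder per block and
    each copied allele is independently redrawn from q_s with probability
    ``mosaic_noise``, which sets the within-block r^2 level and lets LD decay
    with distance across block boundaries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_lines, config.n_markers

    # balanced subpopulation assignment (deterministic)
    subpop = np.arange(n) % config.n_subpops

    # marker map: markers split evenly over chromosomes, sorted uniform cM
    per_chrom = np.full(config.n_chromosomes, p // config.n_chromosomes)
    per_chrom[: p % config.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)
    cm = np.concatenate(
        [np.sort(rng.uniform(0.0, config.map_length_cM, size=k)) for k in per_chrom]
    )
    bp = (cm * 1e6).round().astype(int) + 1

    # ancestral and subpopulation allele frequencies
    p_anc = rng.uniform(config.maf_min, 1.0 - config.maf_min, size=p)
    if config.fst == 0.0:
        q = np.tile(p_anc, (config.n_subpops, 1))
    else:
        a = p_anc * (1.0 - config.fst) / config.fst
        b = (1.0 - p_anc) * (1.0 - config.fst) / config.fst
        q = rng.beta(a, b, size=(config.n_subpops, p))
        q = np.clip(q, 1e-6, 1.0 - 1e-6)

    haplo = np.empty((n, p), dtype=np.int8)
    start = 0
    for chrom_size in per_chrom:
        for size in _block_sizes(int(chrom_size), config.block_size, rng):
            sl = slice(start, start + size)
            # founder pools per subpopulation for this block
            founders = (
                rng.random((config.n_subpops, config.n_founders, size)) < q[:, None, sl]
            ).astype(np.int8)
            choice = rng.integers(0, config.n_founders, size=n)
            block = founders[subpop, choice, :]
            noise_mask = rng.random((n, size)) < config.mosaic_noise
            fresh = (rng.random((n, size)) < q[subpop][:, sl]).astype(np.int8)
            block = np.where(noise_mask, fresh, block)
            haplo[:, sl] = block
            start += size

    dosages = haplo.astype(float) * 2.0  # fully inbred: {0, 2}

    if config.het_rate > 0:
        mask = rng.random(dosages.shape) < config.het_rate
        dosages[mask] = 1.0
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    line_ids = [f"L{i:04d}" for i in range(n)]
    marker_ids = [f"M{i:06d}" for i in range(p)]
    # wheat-style chromosome names (1A..7D) while they last, chrN beyond
    wheat_names = [f"{g}{s}" for g in range(1, 8) for s in "ABD"]
    names = [
        wheat_names[c - 1] if c <= len(wheat_names) else f"chr{c}" for c in chroms
    ]
    marker_map = pd.DataFrame({"marker": marker_ids, "chrom": names, "cM": cm, "bp": bp})
    gm = GenotypeMatrix(dosages, line_ids, marker_ids, marker_map)
    gm.meta.update(
        {"subpop": {lid: int(s) for lid, s in zip(line_ids, subpop)}, "seed": config.seed}
    )
    gm.meta["monomorphic"] = gm.monomorphic_markers()
    return gm


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _draw_effects(tc: TraitConfig, rng: np.random.Generator) -> np.ndarray:
    spec = tc.effect_distribution
    if spec == "gaussian":
        return rng.standard_normal(tc.n_qtl)
    if spec == "equal":
        return np.ones(tc.n_qtl)
    if spec.startswith("geometric:"):
        a = float(spec.split(":", 1)[1])
        return a ** np.arange(tc.n_qtl)
    raise ConfigurationError(f"unknown effect_distribution {spec!r}")


def simulate_trait(geno: GenotypeMatrix, tc: TraitConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a multi-environment phenotype on top of a genotype panel.

    Returns a long-format phenotype table (genotype, environment, trait,
    value) and the :class:`SimTruth` ledger. The residual variance is solved
    from the realized genetic variance so that
    Var(g) / (Var(g) + sigma2_e / nE) equals ``h2_target``.
    """
    tc.validate()
    rng = np.random.default_rng(tc.seed)
    n = geno.n_lines
    if np.isnan(geno.dosages).any():
        raise ValueError("genotypes contain missing calls; run QC/imputation first")

    poly = [m for m in geno.marker_ids if m not in set(geno.monomorphic_markers())]
    if tc.n_qtl > len(poly):
        raise ConfigurationError(
            f"n_qtl={tc.n_qtl} exceeds the {len(poly)} polymorphic markers available"
        )
    qtl = list(rng.choice(poly, size=tc.n_qtl, replace=False)) if tc.n_qtl else []
    effects = _draw_effects(tc, rng)

    cols = [geno.marker_ids.index(m) for m in qtl]
    W = geno.dosages[:, cols] if cols else np.zeros((n, 0))
    Wc = W - W.mean(axis=0, keepdims=True)
    g = Wc @ effects if tc.n_qtl else np.zeros(n)

    epi_ledger: list[tuple[str, str, float]] = []
    for i, j, eff in tc.epistatic_pairs:
        g = g + eff * Wc[:, i] * Wc[:, j]
        epi_ledger.append((qtl[i], qtl[j], float(eff)))

    var_g = float(np.var(g, ddof=1))
    if tc.h2_target > 0 and var_g <= 0:
        raise InfeasibleTraitError(
            "zero genetic variance but h2_target > 0: add QTL or effects"
        )
    if tc.h2_target == 0.0:
        if var_g > 0:
            raise InfeasibleTraitError(
                "h2_target = 0 with non-zero genetic variance is unattainable"
            )
        sigma2_e = 1.0
    elif tc.h2_target == 1.0:
        sigma2_e = 0.0
    else:
        sigma2_e = tc.n_environments * var_g * (1.0 - tc.h2_target) / tc.h2_target

    env_ids = [f"E{j+1}" for j in range(tc.n_environments)]
    env_eff = rng.normal(0.0, np.sqrt(tc.env_variance), size=tc.n_environments)
    resid = rng.normal(0.0, np.sqrt(sigma2_e), size=(n, tc.n_environments))

    values = tc.mu + g[:, None] + env_eff[None, :] + resid
    pheno = pd.DataFrame(
        {
            "genotype": np.repeat(geno.line_ids, tc.n_environments),
            "environment": np.tile(env_ids, n),
            "trait": tc.trait_name,
            "value": values.ravel(),
        }
    )

    var_e_emp = float(np.var(resid, ddof=1)) if sigma2_e > 0 else 0.0
    denom = var_g + var_e_emp / tc.n_environments
    realized = var_g / denom if denom > 0 else 0.0
    truth = SimTruth(
        qtl_markers=[str(m) for m in qtl],
        qtl_effects=np.asarray(effects, dtype=float),
        epistatic_effects=epi_ledger,
        true_genetic_values=pd.Series(g, index=geno.line_ids, name="genetic_value"),
        realized_h2=float(realized),
        sigma2_e=float(sigma2_e),
        h2_target=tc.h2_target,
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# CDS alignments
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def simulate_cds_alignment(
    n_seqs: int, n_codons: int, n_mutations: int, seed: int = 0
) -> tuple[MultipleSeqAlignment, CdsTruth]:
    """Simulate a gapless CDS alignment with a known mutation ledger.

    The reference (first record) starts with ATG and contains no premature
    stop codon. Each mutation is a single-base substitution in a distinct
    codon, never creating a stop, carried by a random non-empty subset of the
    non-reference sequences; the ledger records its synonymous /
    nonsynonymous status from the standard codon table.
    """
    if n_codons < 1:
        raise ConfigurationError("n_codons must be >= 1")
    if n_seqs < 1:
        raise ConfigurationError("n_seqs must be >= 1")
    if n_mutations > n_codons:
        raise ConfigurationError(
            f"n_mutations={n_mutations} exceeds the {n_codons} codons available "
            "(at most one substitution per codon)"
        )
    if n_mutations > 0 and n_seqs < 2:
        raise ConfigurationError("mutations require at least 2 sequences")
    rng = np.random.default_rng(seed)

    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    ref = "".join(codons)

    seqs = [list(ref) for _ in range(n_seqs)]
    records = []
    mut_codons = rng.choice(n_codons, size=n_mutations, replace=False) if n_mutations else []
    for ci in sorted(int(c) for c in np.atleast_1d(mut_codons)):
        ref_codon = codons[ci]
        # rejection-sample a non-stop single-base change
        while True:
            pos = int(rng.integers(0, 3))
            alt_base = _BASES[int(rng.integers(0, 4))]
            if alt_base == ref_codon[pos]:
                continue
            alt_codon = ref_codon[:pos] + alt_base + ref_codon[pos + 1 :]
            if alt_codon not in _STOPS:
                break
        site = ci * 3 + pos
        k = int(rng.integers(1, n_seqs))  # 1 .. n_seqs-1 carriers
        carriers = sorted(int(x) for x in rng.choice(np.arange(1, n_seqs), size=k, replace=False))
        for s in carriers:
            seqs[s][site] = alt_base
        records.append(
            {
                "site": site,
                "codon_index": ci,
                "ref_base": ref_codon[pos],
                "alt_base": alt_base,
                "ref_codon": ref_codon,
                "alt_codon": alt_codon,
                "synonymous": _translate(ref_codon) == _translate(alt_codon),
                "carriers": ",".join(f"seq{s}" for s in carriers),
            }
        )

    aln = MultipleSeqAlignment(
        [
            SeqRecord(Seq("".join(s)), id=f"seq{i}", description="")
            for i, s in enumerate(seqs)
        ]
    )
    ledger = pd.DataFrame(
        records,
        columns=[
            "site",
            "codon_index",
            "ref_base",
            "alt_base",
            "ref_codon",
            "alt_codon",
            "synonymous",
            "carriers",
        ],
    )
    n_hap = len({"".join(s) for s in seqs})
    return aln, CdsTruth(mutations=ledger, n_haplotypes=n_hap)
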