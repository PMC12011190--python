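"""Four-taxon site-category simulator with known admixture truth.

Instead of a coalescent model, each site is independently assigned one of
four categories:

``ils_abba``
    incomplete-lineage-sorting site with the ABBA pattern: all focal-species
    specimens on the P2 lineage side and the donor carry the derived allele.
``ils_baba``
    ILS site with the BABA pattern: the conspecific P1-reference specimen
    and the donor carry the derived allele.
``fixed_diff``
    species-diagnostic fixed difference: only the donor lineage carries the
    derived allele; each focal haplotype independently carries it with
    probability alpha (that individual's admixture proportion).
``invariant_background``
    ancestral everywhere.

With probabilities ``pi_ils`` (split evenly between the two ILS patterns)
and ``pi_fixed``, this yields the closed form

    E[D | alpha] = alpha * pi_fixed / (alpha * pi_fixed + pi_ils)

for a focal specimen tested against the P1 reference under reference-allele
outgroup polarization — the surface every calibration test checks against.
The outgroup allele is the reference base everywhere, matching the
pipeline's polarization convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, SampleRecord, SampleSet, write_vcf

P1_REF_ID = "p1ref"
P3_REF_ID = "p3ref"

CATEGORIES = ("ils_abba", "ils_baba", "fixed_diff", "invariant_background")
_ILS_ABBA, _ILS_BABA, _FIXED, _BACKGROUND = range(4)

#: Spacing between consecutive simulated sites (bp) on the single synthetic
#: chromosome.
SITE_SPACING = 100

_BASES = np.array(list("ACGT"), dtype=object)


@dataclass
class SimParams:
    """Simulation conditions.

    Defaults encode the study-analog cohort: site-category rates
    ``pi_fixed = 0.05`` and ``pi_ils = 0.10``, and admixture proportions
    obtained by inverting the closed-form E[D] against the observed group
    mean D of each ecotype (marine 0.149 -> alpha 0.35; freshwater 0.033 ->
    alpha 0.068).  ``missing_rate`` defaults to 0.01, a typical residual
    missingness for a filtered SNP chart.
    """

    n_sites: int = 2000
    n_marine: int = 5
    n_freshwater: int = 5
    pi_ils: float = 0.10
    pi_fixed: float = 0.05
    alpha_marine: float = 0.35
    alpha_freshwater: float = 0.068
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_marine < 0 or self.n_freshwater < 0:
            raise ValueError("cohort sizes must be non-negative")
        for name in ("pi_ils", "pi_fixed", "alpha_marine", "alpha_freshwater", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pi_ils + self.pi_fixed > 1.0:
            raise ValueError("pi_ils + pi_fixed must not exceed 1")


@dataclass
class SimTruth:
    """Ground truth recorded at generation time."""

    categories: tuple[str, ...]  # per-site category name
    alphas: dict[str, float]  # per focal individual admixture proportion
    fixed_site_indices: tuple[int, ...]  # planted introgression targets

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for c in self.categories:
            counts[c] += 1
        return counts


def simulate(params: SimParams) -> tuple[GenotypeMatrix, SampleSet, SimTruth]:
    """Generate a four-taxon genotype matrix with known admixture truth.

    Samples are ordered ``p1ref, p3ref, marine_*, fresh_*``.  Fully
    reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_sites
    probs = [params.pi_ils / 2, params.pi_ils / 2, params.pi_fixed,
             1.0 - params.pi_ils - params.pi_fixed]
    cat = rng.choice(4, size=n, p=probs)

    marine_ids = [f"marine_{i + 1:03d}" for i in range(params.n_marine)]
    fresh_ids = [f"fresh_{i + 1:03d}" for i in range(params.n_freshwater)]
    sample_ids = [P1_REF_ID, P3_REF_ID] + marine_ids + fresh_ids
    n_focal = params.n_marine + params.n_freshwater
    alphas = [params.alpha_marine] * params.n_marine + [params.alpha_freshwater] * params.n_freshwater

    dos = np.zeros((n, len(sample_ids)), dtype=np.int8)
    is_abba = cat == _ILS_ABBA
    is_baba = cat == _ILS_BABA
    is_fixed = cat == _FIXED
    # P1 reference: derived only at BABA-pattern ILS sites.
    dos[is_baba, 0] = 2
    # Donor (P3) reference: derived at both ILS patterns and at fixed differences.
    dos[is_abba | is_baba | is_fixed, 1] = 2
    # Focal individuals sit on the P2 lineage side: derived at ABBA-pattern
    # ILS sites; at fixed differences each haplotype carries the donor allele
    # independently with probability alpha.
    fixed_idx = np.flatnonzero(is_fixed)
    for j in range(n_focal):
        col = 2 + j
        dos[is_abba, col] = 2
        if fixed_idx.size:
            dos[fixed_idx, col] = rng.binomial(2, alphas[j], size=fixed_idx.size).astype(np.int8)

    if params.missing_rate > 0:
        miss = rng.random(dos.shape) < params.missing_rate
        dos[miss] = MISSING

    pos = 1 + SITE_SPACING * np.arange(n, dtype=np.int64)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4  # always differs from ref
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]

    gm = GenotypeMatrix(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        dosages=dos,
        sample_ids=tuple(sample_ids),
    )
    records = [
        SampleRecord(P1_REF_ID, species="focal", ecotype="NA", role="p1_reference"),
        SampleRecord(P3_REF_ID, species="donor", ecotype="NA", role="p3_reference"),
    ]
    records += [SampleRecord(s, species="focal", ecotype="marine") for s in marine_ids]
    records += [SampleRecord(s, species="focal", ecotype="freshwater") for s in fresh_ids]
    samples = SampleSet(records=tuple(records))
    truth = SimTruth(
        categories=tuple(CATEGORIES[c] for c in cat),
        alphas=dict(zip(marine_ids + fresh_ids, alphas)),
        fixed_site_indices=tuple(int(i) for i in fixed_idx),
    )
    return gm, samples, truth


def expected_d(params: SimParams, alpha: float) -> float:
    """Closed-form E[D] for a focal specimen with admixture ``alpha``.

    Fixed-difference sites contribute ABBA weight ``alpha`` and BABA weight
    0 in expectation; each ILS pattern contributes mass ``pi_ils / 2``, so

        E[D] = alpha * pi_fixed / (alpha * pi_fixed + pi_ils).

    Returns NaN when the denominator is zero.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    denom = alpha * params.pi_fixed + params.pi_ils
    if denom <= 0:
        return float("nan")
    return alpha * params.pi_fixed / denom


#: Half-width (bp) of the toy "gene" drawn around each planted fixed-difference
#: site when writing fixtures.
GENE_PAD = 50


def planted_gene_bed(gm: GenotypeMatrix, truth: SimTruth) -> list[tuple[str, int, int, str]]:
    """Toy gene intervals: one gene around each planted fixed-difference site."""
    rows = []
    for k, si in enumerate(truth.fixed_site_indices):
        pos0 = int(gm.pos[si]) - 1
        start = max(0, pos0 - GENE_PAD)
        end = pos0 + GENE_PAD + 1
        rows.append((str(gm.chrom[si]), start, end, f"gene{k + 1:05d}"))
    return rows


def write_fixture(params: SimParams, out_dir) -> dict[str, Path]:
    """Simulate and write a complete on-disk fixture.

    Emits ``sim.vcf`` (genotypes), ``samples.tsv`` (metadata),
    ``truth.json`` (simulation parameters, per-site categories, per-sample
    admixture, planted site indices and category counts) and ``genes.bed``
    (toy genes around the planted fixed-difference sites).  Returns the
    paths keyed by ``vcf``, ``metadata``, ``truth``, ``bed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm, samples, truth = simulate(params)
    paths = {
        "vcf": out / "sim.vcf",
        "metadata": out / "samples.tsv",
        "truth": out / "truth.json",
        "bed": out / "genes.bed",
    }
    write_vcf(gm, paths["vcf"])
    samples.to_tsv(paths["metadata"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "params": asdict(params),
                "categories": list(truth.categories),
                "alphas": truth.alphas,
                "fixed_site_indices": list(truth.fixed_site_indices),
                "fixed_site_pos": [int(gm.pos[i]) for i in truth.fixed_site_indices],
                "category_counts": truth.category_counts(),
            },
            fh,
            indent=1,
        )
    with open(paths["bed"], "w") as fh:
        for chrom, start, end, name in planted_gene_bed(gm, truth):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    return paths
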