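"""Synthetic multiomics data with the statistical structure of real sequence data.

Genotypes are simulated marker-by-marker from a latent-Gaussian haplotype
model: each haplotype is an AR(1) Gaussian vector over markers, thresholded
at the per-marker minor-allele-frequency quantile, and a genotype is the sum
of two independent haplotypes.  Adjacent-marker correlation of the latent
field emulates linkage disequilibrium; the default MAF law is heavily skewed
toward rare variants (piecewise log-uniform with mass targets of about 35%
below 0.001, 69% below 0.01 and 80% below 0.03, the spectrum typical of a
30-kb sequencing segment).

Expression modalities are i.i.d. Gaussian with variance 0.5.  Phenotypes are
assembled from per-modality effect functions:

  linear        y_i = f1_i + f2_i + eps_i,      f_k = a_k * Phi_k C_k
  interaction   y_i = f1_i + f2_i + Int_i + eps_i,  Int_i = c <f1_i, f2_i>
  nonlinear     f_k(s) = sum_l c_kl [sum_j g_kij^{e_l} cos(a_kl t_j + d_kl1)]
                         sin(a_kl s + d_kl2) * C_k

with Phi_k the exact Dirac design of modality k in a fifth-order B-spline
basis, a_k ~ U(-3, 3) and the phase shifts d ~ U(-pi, pi) redrawn per
replicate, and the triples (a_k1, a_k2, a_k3) = (c_k1, c_k2, c_k3) =
(2/3, -2, 2), e = (1/3, 3/2, 3) fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .basis import BasisSystem, make_bspline_system
from .functional import OmicsVariantFunction, build_variant_function, dirac_design

__all__ = [
    "MAFLaw",
    "GenotypeModel",
    "ScenarioSpec",
    "ScenarioDraws",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_expression",
    "gen_linear_effect",
    "gen_nonlinear_effect",
    "gen_interaction",
    "make_dataset",
]

#: fixed simulation constants
A_TRIPLE = np.array([2.0 / 3.0, -2.0, 2.0])   # (a_k1, a_k2, a_k3)
C_TRIPLE = np.array([2.0 / 3.0, -2.0, 2.0])   # (c_k1, c_k2, c_k3)
E_TRIPLE = np.array([1.0 / 3.0, 1.5, 3.0])    # exponents e_l


@dataclass(frozen=True)
class MAFLaw:
    """Piecewise log-uniform law on (0, 0.5) skewed toward rare variants.

    ``edges`` are bin boundaries and ``probs`` bin masses; within a bin the
    MAF is log-uniform.  The defaults put 34.8% of mass below 0.001, 69.1%
    below 0.01 and 80% below 0.03.
    """

    edges: tuple = (4.5e-4, 1e-3, 1e-2, 3e-2, 0.499)
    probs: tuple = (0.348, 0.343, 0.109, 0.200)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        bins = rng.choice(len(self.probs), size=size, p=np.asarray(self.probs))
        lo = np.asarray(self.edges)[bins]
        hi = np.asarray(self.edges)[bins + 1]
        u = rng.uniform(size=size)
        return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


@dataclass
class GenotypeModel:
    """Latent-Gaussian haplotype model for one genotype modality."""

    n_samples: int = 200
    n_markers: int = 100
    ld_rho: float = 0.9          # AR(1) correlation of the latent field
    maf_law: MAFLaw = field(default_factory=MAFLaw)
    region_length_bp: int = 30_000
    fixed_maf: float | None = None  # override the MAF law (testing/calibration)

    def __post_init__(self):
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")


def simulate_genotypes(model: GenotypeModel, seed: int | np.random.Generator = 0,
                       modality_id: str = "genotype") -> OmicsVariantFunction:
    """Draw a genotype modality: dosages in {0, 1, 2} plus sorted positions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = model.n_markers
    if model.fixed_maf is not None:
        maf = np.full(p, model.fixed_maf)
    else:
        maf = model.maf_law.sample(p, rng)
    thresh = norm.ppf(maf)
    n_hap = 2 * model.n_samples
    z = np.empty((n_hap, p))
    z[:, 0] = rng.standard_normal(n_hap)
    rho = model.ld_rho
    innov_sd = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(n_hap)
    alleles = (z < thresh).astype(float)
    geno = alleles[0::2] + alleles[1::2]
    positions = np.sort(rng.choice(model.region_length_bp, size=p, replace=False)) + 1
    return build_variant_function(geno, positions, modality_id=modality_id)


def simulate_expression(n: int, p2: int, variance: float = 0.5,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Expression levels: i.i.d. N(0, variance) entries (diagonal covariance)."""
    if p2 < 1:
        raise ValueError("p2 must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(variance), size=(n, p2))


# ---------------------------------------------------------------------------
# phenotype transformations
# ---------------------------------------------------------------------------

def _modality_values_positions(modality):
    if isinstance(modality, OmicsVariantFunction):
        return modality.values, modality.positions01
    vals = np.asarray(modality, dtype=float)
    p = vals.shape[1]
    pos = np.array([0.5]) if p == 1 else np.linspace(0.0, 1.0, p)
    return vals, pos


def gen_linear_effect(modality, a_k: float, C_k: np.ndarray,
                      basis: BasisSystem | None = None) -> np.ndarray:
    """Linear effect f_k = a_k * Phi C_k (functional) or a_k * G C_k (matrix).

    For a functional modality Phi = dirac_design in ``basis`` (the integral
    against the B-spline row vector, exact by the Dirac representation);
    C_k maps the J basis scores (or the p2 raw columns) to the phenotype
    dimension.
    """
    C_k = np.atleast_2d(np.asarray(C_k, dtype=float))
    if isinstance(modality, OmicsVariantFunction):
        basis = basis or make_bspline_system()
        design = dirac_design(modality, basis)
    else:
        design = np.asarray(modality, dtype=float)
    if design.shape[1] != C_k.shape[0]:
        raise ValueError(
            f"C_k has {C_k.shape[0]} rows, expected {design.shape[1]}")
    return a_k * design @ C_k


def gen_nonlinear_effect(modality, a_l: np.ndarray, c_l: np.ndarray, e_l: np.ndarray,
                         d1: np.ndarray, d2: np.ndarray, C_k: float,
                         s_points, signed_powers: bool = False) -> np.ndarray:
    """Nonlinear effect evaluated at output points s.

    f_k(s)_i = C_k * sum_l c_l [sum_j g_ij^{e_l} cos(a_l t_j + d1_l)]
               * sin(a_l s + d2_l).

    Fractional exponents require nonnegative inputs (genotype dosages).  With
    ``signed_powers=True`` the power is extended oddly, sign(g) |g|^{e},
    which continuous signed modalities (e.g. expression) use.
    """
    vals, pos = _modality_values_positions(modality)
    s_points = np.atleast_1d(np.asarray(s_points, dtype=float))
    if np.any(vals < 0) and not signed_powers:
        raise ValueError(
            "negative modality values with fractional powers; "
            "use signed_powers=True for signed continuous inputs")
    out = np.zeros((vals.shape[0], s_points.size))
    for l in range(3):
        if signed_powers:
            powered = np.sign(vals) * np.abs(vals) ** e_l[l]
        else:
            powered = vals ** e_l[l]
        inner = powered @ np.cos(a_l[l] * pos + d1[l])          # (n,)
        out += c_l[l] * np.outer(inner, np.sin(a_l[l] * s_points + d2[l]))
    return float(C_k) * out


def gen_interaction(f1: np.ndarray, f2: np.ndarray, c: float = 1.0) -> np.ndarray:
    """Interaction Int = c <f1, f2>: elementwise product of the two effects.

    For a scalar phenotype this is the product of the two integrals; for a
    vector phenotype the product is taken per output coordinate.
    """
    f1 = np.atleast_2d(np.asarray(f1, dtype=float))
    f2 = np.atleast_2d(np.asarray(f2, dtype=float))
    if f1.shape != f2.shape:
        raise ValueError(f"shape mismatch: {f1.shape} vs {f2.shape}")
    return c * f1 * f2


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """Full specification of one simulation scenario."""

    relationship: str = "linear"        # linear | interaction | nonlinear
    omics_config: str = "G-E"           # G-E | G-G
    phenotype_dim: int = 1              # 1 or 50
    noise_var: float = 0.3
    n_samples: int = 200
    p1: int = 100
    p2: int = 1
    interaction_scale: float = 1.0      # the fixed scalar c
    ld_rho: float = 0.9
    expression_var: float = 0.5
    basis_order: int = 5
    basis_n: int = 7

    def __post_init__(self):
        if self.relationship not in ("linear", "interaction", "nonlinear"):
            raise ValueError(f"unknown relationship {self.relationship!r}")
        if self.omics_config not in ("G-E", "G-G"):
            raise ValueError(f"unknown omics_config {self.omics_config!r}")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")

    def basis(self) -> BasisSystem:
        return make_bspline_system(self.basis_order, self.basis_n)


@dataclass
class ScenarioDraws:
    """The per-replicate random coefficients, stored for reproducibility."""

    a: list                      # a_k per modality, U(-3, 3)
    d1: list                     # phase shifts d_kl^(1), U(-pi, pi), 3 per modality
    d2: list                     # phase shifts d_kl^(2)
    C: list                      # coefficient matrices/scalars per modality

    def to_json(self) -> str:
        return json.dumps({
            "a": self.a,
            "d1": [list(d) for d in self.d1],
            "d2": [list(d) for d in self.d2],
            "C": [np.asarray(c).tolist() for c in self.C],
        })


@dataclass
class SimulatedDataset:
    """One realized dataset: modalities, phenotype and its signal components."""

    modalities: list
    y: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    interaction: np.ndarray | None
    eps: np.ndarray
    spec: ScenarioSpec
    draws: ScenarioDraws
    seed: int

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]


def make_dataset(spec: ScenarioSpec, seed: int = 0) -> SimulatedDataset:
    """Generate one replicate of a scenario; fully reproducible from the seed."""
    rng = np.random.default_rng(seed)
    basis = spec.basis()

    g1 = simulate_genotypes(
        GenotypeModel(n_samples=spec.n_samples, n_markers=spec.p1, ld_rho=spec.ld_rho),
        seed=rng, modality_id="G1")
    if spec.omics_config == "G-G":
        m2 = simulate_genotypes(
            GenotypeModel(n_samples=spec.n_samples, n_markers=spec.p1, ld_rho=spec.ld_rho),
            seed=rng, modality_id="G2")
    else:
        m2 = simulate_expression(spec.n_samples, spec.p2, spec.expression_var, seed=rng)
    modalities = [g1, m2]

    a = [float(rng.uniform(-3, 3)) for _ in range(2)]
    d1 = [rng.uniform(-np.pi, np.pi, size=3) for _ in range(2)]
    d2 = [rng.uniform(-np.pi, np.pi, size=3) for _ in range(2)]

    d = spec.phenotype_dim
    effects = []
    if spec.relationship in ("linear", "interaction"):
        C = []
        for m in modalities:
            rows = basis.n_basis if isinstance(m, OmicsVariantFunction) else m.shape[1]
            C.append(rng.standard_normal((rows, d)))
        for k, m in enumerate(modalities):
            effects.append(gen_linear_effect(m, a[k], C[k], basis=basis))
    else:
        C = [float(rng.standard_normal()) for _ in range(2)]
        s_points = np.array([0.5]) if d == 1 else np.linspace(0.0, 1.0, d)
        for k, m in enumerate(modalities):
            signed = not isinstance(m, OmicsVariantFunction)
            effects.append(gen_nonlinear_effect(
                m, A_TRIPLE, C_TRIPLE, E_TRIPLE, d1[k], d2[k], C[k], s_points,
                signed_powers=signed))

    interaction = None
    y = effects[0] + effects[1]
    if spec.relationship == "interaction":
        interaction = gen_interaction(effects[0], effects[1], spec.interaction_scale)
        y = y + interaction

    eps = rng.normal(0.0, np.sqrt(spec.noise_var), size=(spec.n_samples, d))
    y = y + eps

    return SimulatedDataset(
        modalities=modalities, y=y, y1=effects[0], y2=effects[1],
        interaction=interaction, eps=eps, spec=spec,
        draws=ScenarioDraws(a=a, d1=d1, d2=d2, C=C), seed=seed)


# ---------------------------------------------------------------------------
# plain-text export
# ---------------------------------------------------------------------------

def write_genotypes_vcf(ovf: OmicsVariantFunction, path, contig: str = "1",
                        region_offset: int = 0) -> None:
    """Write a genotype modality as an uncompressed VCF (GT field only)."""
    vals = ovf.values.astype(int)
    # recover bp-like integer positions from the rescaled coordinates
    span = max(1, ovf.n_markers * 100)
    pos = (ovf.positions01 * span).astype(int) + 1 + region_offset
    pos = np.maximum.accumulate(pos)  # monotone after rounding
    pos += np.arange(ovf.n_markers)   # strictly increasing
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"S{i}" for i in range(ovf.n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(ovf.n_markers):
            gts = "\t".join(gt_map[int(v)] for v in vals[:, j])
            fh.write(f"{contig}\t{pos[j]}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def export_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write a dataset as plain text: VCF/TSV modalities, TSV phenotype, JSON sidecar."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for k, m in enumerate(ds.modalities):
        if isinstance(m, OmicsVariantFunction):
            write_genotypes_vcf(m, os.path.join(outdir, f"modality{k + 1}.vcf"))
        else:
            np.savetxt(os.path.join(outdir, f"modality{k + 1}.tsv"), m, delimiter="\t")
    np.savetxt(os.path.join(outdir, "phenotype.tsv"), ds.y, delimiter="\t")
    sidecar = {
        "spec": asdict(ds.spec),
        "seed": ds.seed,
        "draws": json.loads(ds.draws.to_json()),
    }
    with open(os.path.join(outdir, "scenario.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
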