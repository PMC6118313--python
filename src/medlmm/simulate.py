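"""Synthetic genotypes, mediators, phenotypes and expression panels.

Every pipeline stage is exercised on data with known ground truth:

* genotypes follow a Balding–Nichols two-level allele-frequency model
  (inbred lines are effectively haploid, so one 0/1 call per line), with a
  divergence parameter playing the role of F_ST between subpopulations —
  this is what induces the kinship confounding the mixed models correct;
* mediator and phenotype follow the two-equation mediation model
  ``M = X b1 + Z g1 + eM`` and ``Y = X b2 + M t1 + Z g2 + eY`` with
  standardized background SNPs Z, i.i.d. normal background effects whose
  scale is chosen so the implied background-to-noise ratios match the
  requested ``lambda1``/``lambda2``, and optionally correlated g1/g2
  (shared background loci) to generate confounding;
* expression panels combine gene-local (cis) genotype signal, shared latent
  factors planting a correlation backbone, and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import SNP, GenotypeMatrix, standardize, standardize_columns

__all__ = [
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_mediation",
    "simulate_expression_panel",
]

CHROM_LENGTH = 30_000_000  # synthetic chromosome size, bp


@dataclass
class SimulationTruth:
    """Generative parameters recorded alongside each simulated dataset."""

    seed: int
    beta1: float = 0.0
    beta2: float = 0.0
    theta1: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    rho_gamma: float = 0.0
    causal_snp_index: int = -1
    gamma1: np.ndarray | None = None
    gamma2: np.ndarray | None = None
    network_backbone: list[tuple[str, str]] = field(default_factory=list)
    cis_fraction: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "theta1": self.theta1,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "rho_gamma": self.rho_gamma,
            "causal_snp_index": self.causal_snp_index,
            "network_backbone": [list(e) for e in self.network_backbone],
            "cis_fraction": self.cis_fraction,
        }
        return d


def simulate_genotypes(
    n_lines: int,
    n_snps: int,
    n_pops: int = 2,
    divergence: float = 0.3,
    seed: int = 0,
    n_chrom: int = 5,
    min_maf: float = 0.02,
) -> GenotypeMatrix:
    """Balding–Nichols genotypes for ``n_lines`` haploid-equivalent lines.

    Ancestral allele frequencies are U(0.1, 0.9); each of ``n_pops``
    subpopulations draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F)
    with F = ``divergence`` (F = 0 gives an unstructured panel). Lines are
    assigned to populations in equal blocks and drawn i.i.d. within them.
    SNPs monomorphic in the realized sample are redrawn where possible so
    every column carries variation.
    """
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    pops = np.repeat(np.arange(n_pops), int(np.ceil(n_lines / n_pops)))[:n_lines]
    p_anc = rng.uniform(0.1, 0.9, size=n_snps)
    if divergence > 0:
        a = p_anc * (1.0 - divergence) / divergence
        b = (1.0 - p_anc) * (1.0 - divergence) / divergence
        p_pop = rng.beta(a[None, :], b[None, :], size=(n_pops, n_snps))
    else:
        p_pop = np.tile(p_anc, (n_pops, 1))
    calls = (rng.random((n_lines, n_snps)) < p_pop[pops, :]).astype(float)
    # redraw near-monomorphic columns; if the drawn population frequencies
    # are themselves extreme, redraw those too
    for round_ in range(40):
        freq = calls.mean(axis=0)
        bad = np.flatnonzero(np.minimum(freq, 1 - freq) < min_maf)
        if bad.size == 0:
            break
        if round_ >= 3:
            p_anc[bad] = rng.uniform(0.1, 0.9, size=bad.size)
            if divergence > 0:
                a = p_anc[bad] * (1.0 - divergence) / divergence
                b = (1.0 - p_anc[bad]) * (1.0 - divergence) / divergence
                p_pop[:, bad] = rng.beta(a[None, :], b[None, :], size=(n_pops, bad.size))
            else:
                p_pop[:, bad] = np.tile(p_anc[bad], (n_pops, 1))
        calls[:, bad] = (
            rng.random((n_lines, bad.size)) < p_pop[pops][:, bad]
        ).astype(float)
    chroms = np.sort(rng.integers(0, n_chrom, size=n_snps))
    positions = np.empty(n_snps, dtype=int)
    for c in range(n_chrom):
        idx = np.flatnonzero(chroms == c)
        positions[idx] = np.sort(
            rng.choice(np.arange(1, CHROM_LENGTH), size=idx.size, replace=False)
        )
    snps = [
        SNP(f"chr{chroms[j] + 1}", int(positions[j]), f"chr{chroms[j] + 1}:{positions[j]}")
        for j in range(n_snps)
    ]
    lines = [f"line{i:04d}" for i in range(n_lines)]
    g = GenotypeMatrix(lines=lines, snps=snps, calls=calls)
    g.populations = pops  # type: ignore[attr-defined]
    return g


def _background_pair(
    rng: np.random.Generator,
    p: int,
    scale1: float,
    scale2: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated per-SNP background effect vectors (shared loci model)."""
    z1 = rng.standard_normal(p)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(p)
    return scale1 * z1, scale2 * z2


def simulate_mediation(
    g: GenotypeMatrix,
    beta1: float = 0.4,
    beta2: float = 0.25,
    theta1: float = 0.51,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    rho_gamma: float = 0.5,
    causal_snp_index: int | None = None,
    sigma_m2: float | None = None,
    sigma_y2: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """Draw (mediator, phenotype) from the two-equation mediation model.

    The focal SNP X is the standardized causal column; the standardized
    remaining columns form Z. Background effects have per-SNP variance
    ``sigma_i^2 / p`` so that the realized background-to-noise variance
    ratio matches ``lambda1`` / ``lambda2`` in expectation.

    By default the noise variances ``sigma_m2`` / ``sigma_y2`` are chosen
    so that ``m`` and ``y`` have unit variance in expectation: the effect
    parameters are then on the same standardized scale the fitting stages
    use, so recovered estimates are directly comparable with the truth.
    Pass explicit noise variances to override.
    """
    rng = np.random.default_rng(seed)
    n, p = g.n_lines, g.n_snps
    if causal_snp_index is None:
        # pick the most common-frequency SNP for a well-powered focal variant
        causal_snp_index = int(np.argmin(np.abs(g.maf() - 0.4)))
    if not 0 <= causal_snp_index < p:
        raise ValueError("causal_snp_index out of range")
    x = standardize(g.calls[:, causal_snp_index])
    others = np.delete(np.arange(p), causal_snp_index)
    z = standardize_columns(g.calls[:, others])
    p_bg = z.shape[1]
    if sigma_m2 is None:
        # var(m) = beta1^2 + (1 + lambda1) sigma_m2 = 1
        sigma_m2 = max(1.0 - beta1**2, 1e-6) / (1.0 + lambda1)
    if sigma_y2 is None:
        # var(y) = a + 2 t1 rho sqrt(l1 sM2 l2) s + (1 + lambda2) s^2 = 1
        # with a = var(b2 x + t1 m) and s = sqrt(sigma_y2)
        a = beta2**2 + theta1**2 + 2.0 * beta1 * beta2 * theta1
        c2 = 1.0 + lambda2
        c1 = 2.0 * theta1 * rho_gamma * np.sqrt(lambda1 * sigma_m2 * lambda2)
        c0 = a - 1.0
        disc = c1**2 - 4.0 * c2 * c0
        if disc <= 0 or a >= 1.0:
            raise ValueError(
                "requested effects imply var(y) >= 1 before noise; pass "
                "sigma_y2 explicitly for an unnormalized simulation"
            )
        s = (-c1 + np.sqrt(disc)) / (2.0 * c2)
        sigma_y2 = max(s, 1e-3) ** 2
    scale1 = np.sqrt(lambda1 * sigma_m2 / p_bg)
    scale2 = np.sqrt(lambda2 * sigma_y2 / p_bg)
    gamma1, gamma2 = _background_pair(rng, p_bg, scale1, scale2, rho_gamma)
    m = beta1 * x + z @ gamma1 + rng.normal(0.0, np.sqrt(sigma_m2), n)
    y = beta2 * x + theta1 * m + z @ gamma2 + rng.normal(0.0, np.sqrt(sigma_y2), n)
    truth = SimulationTruth(
        seed=seed,
        beta1=beta1,
        beta2=beta2,
        theta1=theta1,
        lambda1=lambda1,
        lambda2=lambda2,
        rho_gamma=rho_gamma,
        causal_snp_index=causal_snp_index,
        gamma1=gamma1,
        gamma2=gamma2,
    )
    return m, y, truth


def simulate_expression_panel(
    g: GenotypeMatrix,
    n_genes: int,
    backbone: list[tuple[int, int]] | None = None,
    cis_fraction: float = 0.4,
    backbone_fraction: float = 0.4,
    trans_hub: tuple[int, list[int]] | None = None,
    flank: int = 15_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Expression panel with planted cis architecture and correlation backbone.

    Each gene's expression is a standardized mixture::

        expr_j = sqrt(cis) * local_score_j + sqrt(bb) * factor_c(j) + sqrt(rest) * noise

    where ``local_score_j`` is a weighted sum of the SNPs within ``flank`` of
    the gene body (the cis signal a local-kinship variance component should
    recover), ``factor_c(j)`` is a latent factor shared by the genes of the
    clique containing j (planting pairwise correlations for the network
    stage), and ``trans_hub=(k, targets)`` routes gene k's local score into
    the listed target genes (a trans-acting hub).

    Returns (expression DataFrame, gene annotation DataFrame with columns
    chrom/start/end, truth). Gene bodies are placed away from chromosome
    edges with 2 kb span.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    n = g.n_lines
    positions = np.array([s.pos for s in g.snps])
    chroms = np.array([s.chrom for s in g.snps])
    # anchor each gene at a randomly chosen SNP so local windows are non-empty
    anchor = rng.choice(g.n_snps, size=n_genes, replace=False)
    ann = pd.DataFrame(
        {
            "chrom": chroms[anchor],
            "start": np.maximum(positions[anchor] - 1000, 1),
            "end": positions[anchor] + 1000,
        },
        index=[f"gene{j:03d}" for j in range(n_genes)],
    )
    ann.index.name = "gene_id"

    local_scores = np.empty((n, n_genes))
    for j in range(n_genes):
        lo = ann["start"].iloc[j] - flank
        hi = ann["end"].iloc[j] + flank
        sel = np.flatnonzero(
            (chroms == ann["chrom"].iloc[j]) & (positions >= lo) & (positions <= hi)
        )
        w = rng.standard_normal(sel.size)
        score = standardize_columns(g.calls[:, sel]) @ w
        local_scores[:, j] = standardize(score)

    cliques: list[list[int]] = []
    if backbone:
        seen: dict[int, int] = {}
        for a, b in backbone:
            ca, cb = seen.get(a), seen.get(b)
            if ca is None and cb is None:
                cliques.append([a, b])
                seen[a] = seen[b] = len(cliques) - 1
            elif ca is None:
                cliques[cb].append(a)
                seen[a] = cb
            elif cb is None:
                cliques[ca].append(b)
                seen[b] = ca
    factors = rng.standard_normal((n, max(len(cliques), 1)))

    expr = np.empty((n, n_genes))
    member = {j: c for c, genes in enumerate(cliques) for j in genes}
    for j in range(n_genes):
        comp = np.sqrt(cis_fraction) * local_scores[:, j]
        bb = backbone_fraction if j in member else 0.0
        if bb:
            comp = comp + np.sqrt(bb) * standardize(factors[:, member[j]])
        noise_var = max(1.0 - cis_fraction - bb, 0.0)
        comp = comp + np.sqrt(noise_var) * rng.standard_normal(n)
        expr[:, j] = comp
    if trans_hub is not None:
        k, targets = trans_hub
        for t in targets:
            expr[:, t] = expr[:, t] + 0.8 * local_scores[:, k]

    edges = [
        (ann.index[a], ann.index[b])
        for genes in cliques
        for i, a in enumerate(genes)
        for b in genes[i + 1 :]
    ]
    truth = SimulationTruth(
        seed=seed,
        network_backbone=edges,
        cis_fraction={gid: cis_fraction for gid in ann.index},
    )
    expr_df = pd.DataFrame(expr, index=list(g.lines), columns=list(ann.index))
    expr_df.index.name = "line"
    return expr_df, ann, truth
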