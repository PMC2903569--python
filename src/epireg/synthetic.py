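"""Synthetic panels with the statistical structure the pipeline assumes.

The generator emulates a promoter-methylation screen on a breast-cancer
cell-line panel: CpG sites fall in tight clumps along chromosomes
(intra-clump spacing far below the 2,000 bp proximity threshold,
inter-clump gaps far above it); within a clump, sub-groups of sites share
a latent methylation profile plus independent noise, clipped to [0, 100];
cell lines are correlated through shared latent factors; and a minority
of genes are "regulated": their expression is a decreasing logistic
function of their promoter sub-group's methylation.  Expression is
emitted on log2 scale so the pipeline's de-log + global min-max
normalization is exercised end to end; two anchor values pin the global
minimum and maximum so normalization exactly inverts the emission map.

Defaults are sized to roughly 1/100 of a genome-wide screen (45 lines,
~1,400 sites, 60 genes, 15% regulated) so full-pipeline runs stay fast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import ExpressionProbeSet, MethylationSite, Panel, SyntheticTruth
from . import io as eio

# The 45-line breast cancer panel shared by the methylation and expression
# screens this generator emulates.
DEFAULT_CELL_LINES = (
    "600MPE", "AU565", "BT20", "BT474", "BT483",
    "BT549", "CAMA1", "DU4475", "HBL100", "HCC1143",
    "HCC1187", "HCC1428", "HCC1500", "HCC1569", "HCC1599",
    "HCC1937", "HCC1954", "HCC202", "HCC2185", "HCC38",
    "HCC3153", "HCC70", "HS578T", "LY2", "MCF10A",
    "MCF12A", "MCF7", "MDAMB157", "MDAMB231", "MDAMB361",
    "MDAMB415", "MDAMB435", "MDAMB453", "MDAMB468", "SKBR3",
    "SUM1315", "SUM149PT", "SUM159PT", "SUM185PE", "SUM44PE",
    "SUM52PE", "T47D", "UACC812", "ZR751", "ZR75B",
)

N_CHROMOSOMES = 5
N_LATENT_FACTORS = 5          # shared line-correlation factors
INTRA_CLUMP_MEAN_BP = 80      # mean spacing between sites in a clump
INTER_CLUMP_GAP_BP = 45_000   # minimum gap between clumps (>> proximity threshold
                              # plus probe offset + association window)
LOG_OFFSET = 1.0              # decimal = normalized value + offset before log2


@dataclass
class PanelData:
    """In-memory result of :func:`simulate_panel`."""

    sites: list[MethylationSite]
    probesets: list[ExpressionProbeSet]
    panel: Panel
    truth: SyntheticTruth


def _panel_names(n_lines: int) -> tuple[str, ...]:
    names = list(DEFAULT_CELL_LINES[:n_lines])
    for i in range(len(names), n_lines):
        names.append(f"LINE{i + 1:03d}")
    return tuple(sorted(names))


def simulate_panel(
    n_lines: int = 45,
    n_genes: int = 60,
    frac_regulated: float = 0.15,
    sites_per_region: int = 23,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> PanelData:
    """Generate a paired methylation/expression panel with known ground truth.

    ``frac_regulated`` of the genes get expression following a decreasing
    logistic of their promoter sub-group's latent methylation; the rest are
    null (expression independent of methylation).  Fully determined by
    ``seed``.
    """
    if not 0.0 <= frac_regulated <= 1.0:
        raise ValueError("frac_regulated must be in [0, 1]")
    if n_lines < 4:
        raise ValueError("need at least 4 cell lines")
    if sites_per_region < 1 or n_genes < 1:
        raise ValueError("n_genes and sites_per_region must be positive")
    rng = np.random.default_rng(seed)
    names = _panel_names(n_lines)
    panel = Panel(names)

    # shared latent factors induce inter-line correlation
    F = rng.normal(0.0, 1.0, size=(N_LATENT_FACTORS, n_lines))

    n_reg = int(round(frac_regulated * n_genes))
    reg_flags = np.zeros(n_genes, dtype=bool)
    reg_flags[rng.choice(n_genes, size=n_reg, replace=False)] = True

    sites: list[MethylationSite] = []
    probesets: list[ExpressionProbeSet] = []
    region_of_site: dict[str, int] = {}
    cluster_of_site: dict[str, int] = {}
    curve_params: dict[str, tuple[float, float, float]] = {}
    regulated: list[str] = []
    expr_values: list[np.ndarray] = []

    chrom_cursor = {c: 10_000 for c in range(N_CHROMOSOMES)}
    site_counter = 0
    global_cluster = 0
    for g in range(n_genes):
        gene = f"GENE{g:04d}"
        chrom_idx = g % N_CHROMOSOMES
        chrom = f"chr{chrom_idx + 1:02d}"
        pos = chrom_cursor[chrom_idx] + INTER_CLUMP_GAP_BP + int(rng.exponential(20_000))

        n_sub = int(rng.integers(2, 4)) if sites_per_region >= 2 else 1
        n_sub = min(n_sub, sites_per_region)
        # promoter sub-group: wide methylation spread for curve identifiability
        latents = np.empty((n_sub, n_lines))
        w = rng.normal(0.0, 25.0 / np.sqrt(N_LATENT_FACTORS), N_LATENT_FACTORS)
        latents[0] = np.clip(50.0 + w @ F + rng.normal(0, 10.0, n_lines), 0.0, 100.0)
        for s in range(1, n_sub):
            mu = rng.uniform(10.0, 90.0)
            w = rng.normal(0.0, 15.0 / np.sqrt(N_LATENT_FACTORS), N_LATENT_FACTORS)
            latents[s] = np.clip(mu + w @ F + rng.normal(0, 8.0, n_lines), 0.0, 100.0)

        sub_of = np.arange(sites_per_region) % n_sub  # interleaved membership
        first_pos = pos
        for i in range(sites_per_region):
            profile = np.clip(
                latents[sub_of[i]] + rng.normal(0.0, noise_sd, n_lines), 0.0, 100.0
            )
            sid = f"cg{site_counter:06d}"
            site_counter += 1
            sites.append(MethylationSite(sid, chrom, pos, profile))
            region_of_site[sid] = g
            cluster_of_site[sid] = global_cluster + int(sub_of[i])
            pos += 1 + int(rng.poisson(INTRA_CLUMP_MEAN_BP))
        global_cluster += n_sub
        clump_end = sites[-1].position

        # probe set downstream of the clump, inside the association window
        p_start = clump_end + int(rng.uniform(500, 15_000))
        p_end = p_start + int(rng.uniform(500, 3_000))
        if reg_flags[g]:
            a = rng.uniform(60.0, 95.0)
            b = rng.uniform(0.08, 0.25)
            c = float(np.clip(np.median(latents[0]) + rng.uniform(-10, 10), 20.0, 80.0))
            E = a / (1.0 + np.exp(np.clip(b * (latents[0] - c), -500, 500)))
            E = np.clip(E + rng.normal(0.0, noise_sd, n_lines), 0.0, 100.0)
            regulated.append(gene)
            curve_params[gene] = (float(a), float(b), float(c))
        else:
            E = rng.uniform(5.0, 95.0, n_lines)
        expr_values.append(E)
        probesets.append(
            ExpressionProbeSet(f"ps{g:04d}", gene, chrom, p_start, p_end, E.copy())
        )
        chrom_cursor[chrom_idx] = p_end

    # pin the global normalized range to exactly [0, 100] so the pipeline's
    # de-log + min-max normalization inverts the emission map below
    null_idx = [g for g in range(n_genes) if not reg_flags[g]]
    if null_idx:
        tgt = null_idx[0]
        v = probesets[tgt].profile
        v[int(np.argmin(v))] = 0.0
        v[int(np.argmax(v))] = 100.0
    else:
        warnings.warn(
            "no null genes to anchor the normalization range; "
            "normalized expression will be an affine distortion of the truth"
        )

    # emit expression on log2 scale: decimal = value + LOG_OFFSET
    for p in probesets:
        p.profile = np.log2(p.profile + LOG_OFFSET)

    # emit in the readers' canonical order so files round-trip bit-identically
    sites.sort(key=lambda s: (s.chromosome, s.position, s.site_id))
    probesets.sort(key=lambda p: (p.chromosome, p.start, p.probeset_id))

    truth = SyntheticTruth(
        seed=seed,
        region_of_site=region_of_site,
        cluster_of_site=cluster_of_site,
        regulated_genes=regulated,
        curve_params=curve_params,
        noise_sd=noise_sd,
    )
    return PanelData(sites=sites, probesets=probesets, panel=panel, truth=truth)


def generate_panel(
    outdir: str | Path,
    n_lines: int = 45,
    n_genes: int = 60,
    frac_regulated: float = 0.15,
    sites_per_region: int = 23,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[Path, Path, SyntheticTruth]:
    """Write methylation/expression TSVs plus a truth JSON; returns the paths.

    Byte-identical across runs with the same arguments.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_panel(n_lines, n_genes, frac_regulated, sites_per_region, noise_sd, seed)
    meth = outdir / "methylation.tsv"
    expr = outdir / "expression.tsv"
    eio.write_methylation(meth, data.sites, data.panel)
    eio.write_expression(expr, data.probesets, data.panel)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            dict(
                seed=data.truth.seed,
                noise_sd=data.truth.noise_sd,
                regulated_genes=data.truth.regulated_genes,
                curve_params={g: list(v) for g, v in data.truth.curve_params.items()},
                region_of_site=data.truth.region_of_site,
                cluster_of_site=data.truth.cluster_of_site,
            ),
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    (outdir / "panel.tsv").write_text("".join(f"{c}\n" for c in data.panel.cell_lines))
    return meth, expr, data.truth


def generate_circles(
    n_per_ring: int = 100,
    radii: tuple[float, ...] = (1.0, 3.0, 5.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled 2-D points on concentric circles (a nonlinear-boundary testbed).

    Angles are uniform; the radius of a ring-i point is Normal(radii[i],
    noise_sd).  Returns (points, ring labels).  Warns if adjacent rings are
    close enough to overlap at the given noise.
    """
    radii = tuple(float(r) for r in radii)
    if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    gaps = [r2 - r1 for r1, r2 in zip(radii, radii[1:])]
    if gaps and noise_sd > 0 and min(gaps) < 6 * noise_sd:
        warnings.warn("rings may overlap at this noise level")
    rng = np.random.default_rng(seed)
    pts = []
    labels = []
    for i, r in enumerate(radii):
        theta = rng.uniform(0.0, 2.0 * np.pi, n_per_ring)
        rr = rng.normal(r, noise_sd, n_per_ring) if noise_sd > 0 else np.full(n_per_ring, r)
        pts.append(np.column_stack([rr * np.cos(theta), rr * np.sin(theta)]))
        labels.append(np.full(n_per_ring, i, dtype=int))
    return np.vstack(pts), np.concatenate(labels)
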