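"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are simulated directly — no individual-level genotypes —
for standardized (unit-variance) traits measured in two independent
cohorts, mirroring the two-sample design where exposure (cytokine) effects
come from one population and outcome (sarcopenia/aging trait) effects from
another:

* SNP j draws a minor-allele frequency p_j ~ Uniform(maf_range) and a true
  exposure effect gamma_j with magnitude ~ Uniform(gamma_range) and random
  sign;
* sampling SEs follow the standard large-sample law for a per-allele
  regression on a unit-variance trait, se = [2 p (1-p) N]^(-1/2), with the
  exposure and outcome panel sizes;
* observed effects are beta_x ~ N(gamma_j, se_x^2) and
  beta_y ~ N(beta * gamma_j + alpha_j, se_y^2), where beta is the true
  causal effect and alpha_j a direct (pleiotropic) outcome effect: zero for
  valid SNPs, ~ N(pleiotropy_mean, pleiotropy_sd^2) *in the
  exposure-increasing allele orientation* for the configured invalid
  fraction (non-zero mean = directional pleiotropy; defining the direction
  relative to sign(gamma_j) keeps it meaningful whichever allele is
  labelled the effect allele);
* p-values are two-sided z-tests; EAF is reported as the true MAF (optional
  sampling noise via ``eaf_noise``);
* a configured fraction of SNPs receives palindromic (A/T or C/G) allele
  pairs; LD blocks are emitted as block-constant r2 entries; a configured
  fraction is annotated to a confounder trait.

Default sample sizes are the cytokine-GWAS cohort (8,293) and the
grip-strength meta-GWAS (254,894) scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import ConfounderTable, GwasDataset, LDTable, write_summary_stats

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generative specification for one exposure-outcome pair."""

    n_snps: int = 50
    n_exposure: int = 8293
    n_outcome: int = 254894
    true_beta: float = 0.1
    gamma_range: tuple[float, float] = (0.1, 0.3)
    maf_range: tuple[float, float] = (0.1, 0.4)
    prop_invalid: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    prop_palindromic: float = 0.0
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    confounder_fraction: float = 0.0
    eaf_noise: bool = False
    seed: int = 0
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("prop_invalid", "prop_palindromic", "confounder_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if hi >= 0.5 and self.prop_palindromic > 0.0:
            warnings.warn(
                "MAF at 0.5 makes palindromic strand frequency-ambiguous",
                stacklevel=2,
            )


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def _positions(cfg: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray, list]:
    """Chromosome/position layout plus LD entries.

    LD-block members sit 1 kb apart on one chromosome (inside the clumping
    window); all other SNPs are 20 Mb apart (outside it).
    """
    chrom = np.empty(cfg.n_snps, dtype=object)
    pos = np.empty(cfg.n_snps, dtype=np.int64)
    ld_entries = []
    i = 0
    chrom_cycle = 0
    for size, r2 in cfg.ld_blocks:
        size = min(size, cfg.n_snps - i)
        if size <= 0:
            break
        c = str(chrom_cycle % 22 + 1)
        base = 1_000_000 + 30_000_000 * (chrom_cycle // 22)
        for k in range(size):
            chrom[i + k] = c
            pos[i + k] = base + 1000 * k
        for a in range(size):
            for b in range(a + 1, size):
                ld_entries.append((i + a, i + b, r2))
        i += size
        chrom_cycle += 1
    while i < cfg.n_snps:
        chrom[i] = str(chrom_cycle % 22 + 1)
        pos[i] = 1_000_000 + 20_000_000 * (chrom_cycle // 22 + 1)
        i += 1
        chrom_cycle += 1
    return chrom, pos, ld_entries


def simulate_dataset_pair(
    cfg: SimulationConfig,
) -> tuple[GwasDataset, GwasDataset, LDTable, ConfounderTable, pd.DataFrame]:
    """Generate an exposure/outcome dataset pair with a truth table.

    Returns (exposure, outcome, ld, confounders, truth); ``truth`` has one
    row per SNP with gamma, alpha, valid flag, MAF and annotation flags.
    All randomness comes from a single generator seeded by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps
    snp_ids = np.array([f"rs{100000 + i}" for i in range(j)])
    maf = rng.uniform(*cfg.maf_range, size=j)
    gamma = rng.uniform(*cfg.gamma_range, size=j) * rng.choice([-1.0, 1.0], size=j)
    invalid = rng.random(j) < cfg.prop_invalid
    # pleiotropy direction is defined in the exposure-increasing allele
    # orientation: a non-zero mean must shift every invalid SNP's Wald
    # ratio the same way regardless of which allele is labelled "effect"
    alpha = np.where(
        invalid,
        np.sign(gamma) * rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=j),
        0.0,
    )

    het = 2.0 * maf * (1.0 - maf)
    se_x = (het * cfg.n_exposure) ** -0.5
    se_y = (het * cfg.n_outcome) ** -0.5
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.true_beta * gamma + alpha, se_y)

    palindromic = rng.random(j) < cfg.prop_palindromic
    allele_pairs = [
        _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
        if pal
        else _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        for pal in palindromic
    ]
    ea = np.array([p[0] for p in allele_pairs])
    oa = np.array([p[1] for p in allele_pairs])

    chrom, pos, ld_idx = _positions(cfg, rng)
    ld = LDTable((snp_ids[a], snp_ids[b], r2) for a, b, r2 in ld_idx)

    confounded = rng.random(j) < cfg.confounder_fraction
    conf = ConfounderTable()
    conf_traits = ["BMI", "age", "sex", "weight"]
    for i in np.flatnonzero(confounded):
        conf.add(snp_ids[i], conf_traits[int(rng.integers(len(conf_traits)))])

    if cfg.eaf_noise:
        eaf_x = np.clip(
            rng.normal(maf, np.sqrt(maf * (1 - maf) / (2 * cfg.n_exposure))),
            1e-4,
            1 - 1e-4,
        )
    else:
        eaf_x = maf

    def _dataset(name, beta, se, n):
        return GwasDataset(
            trait_name=name,
            records=pd.DataFrame(
                dict(
                    snp_id=snp_ids,
                    chrom=chrom,
                    pos=pos,
                    effect_allele=ea,
                    other_allele=oa,
                    eaf=eaf_x,
                    beta=beta,
                    se=se,
                    pval=np.clip(_two_sided_p(beta, se), np.finfo(float).tiny, 1.0),
                    n=np.full(j, n, dtype=np.int64),
                )
            ),
        )

    exposure = _dataset(cfg.exposure_name, beta_x, se_x, cfg.n_exposure)
    outcome = _dataset(cfg.outcome_name, beta_y, se_y, cfg.n_outcome)
    truth = pd.DataFrame(
        dict(
            snp_id=snp_ids,
            gamma=gamma,
            alpha=alpha,
            valid=~invalid,
            maf=maf,
            palindromic=palindromic,
            confounded=confounded,
        )
    )
    return exposure, outcome, ld, conf, truth


def instruments_from_truth(
    exposure: GwasDataset, outcome: GwasDataset
) -> pd.DataFrame:
    """Directly harmonize a simulated pair (alleles are already aligned).

    Convenience for estimator-level simulation studies that bypass the
    selection pipeline.
    """
    from .harmonize import harmonize_pair

    instruments, _ = harmonize_pair(exposure, outcome, drop_palindromic=False)
    return instruments


def simulate_bidirectional_pair(
    beta_forward: float,
    beta_reverse: float,
    n_snps: int = 30,
    n_x: int = 8293,
    n_y: int = 50000,
    gamma_range_x: tuple[float, float] = (0.15, 0.25),
    gamma_range_y: tuple[float, float] = (0.1, 0.3),
    maf_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    x_name: str = "cytokine",
    y_name: str = "trait",
) -> tuple[GwasDataset, GwasDataset, LDTable, ConfounderTable, pd.DataFrame]:
    """Two traits, each with its own instrument panel, causal both ways.

    Trait X causes trait Y with effect ``beta_forward`` through X's
    instruments; Y causes X with ``beta_reverse`` through Y's instruments
    (0 for a unidirectional fixture). Each trait's dataset contains both
    panels, so forward and reverse selection see realistic candidates. The
    forward effect size is kept small enough that X's instruments are not
    discarded by the outcome-association filter.
    """
    rng = np.random.default_rng(seed)
    jx = jy = n_snps
    ids_x = np.array([f"rsx{200000 + i}" for i in range(jx)])
    ids_y = np.array([f"rsy{300000 + i}" for i in range(jy)])
    maf = rng.uniform(*maf_range, size=jx + jy)
    het = 2.0 * maf * (1.0 - maf)
    gamma_x = rng.uniform(*gamma_range_x, size=jx) * rng.choice([-1.0, 1.0], size=jx)
    gamma_y = rng.uniform(*gamma_range_y, size=jy) * rng.choice([-1.0, 1.0], size=jy)

    se_on_x = (het * n_x) ** -0.5
    se_on_y = (het * n_y) ** -0.5
    # true marginal effects of every SNP on each trait
    mu_x = np.concatenate([gamma_x, beta_reverse * gamma_y])
    mu_y = np.concatenate([beta_forward * gamma_x, gamma_y])
    beta_on_x = rng.normal(mu_x, se_on_x)
    beta_on_y = rng.normal(mu_y, se_on_y)

    snp_ids = np.concatenate([ids_x, ids_y])
    n_total = jx + jy
    chrom = np.array([str(i % 22 + 1) for i in range(n_total)], dtype=object)
    pos = np.array(
        [1_000_000 + 20_000_000 * (i // 22 + 1) for i in range(n_total)],
        dtype=np.int64,
    )
    ea = np.array(["A"] * n_total)
    oa = np.array(["G"] * n_total)

    def _dataset(name, beta, se, n):
        return GwasDataset(
            trait_name=name,
            records=pd.DataFrame(
                dict(
                    snp_id=snp_ids,
                    chrom=chrom,
                    pos=pos,
                    effect_allele=ea,
                    other_allele=oa,
                    eaf=maf,
                    beta=beta,
                    se=se,
                    pval=np.clip(
                        _two_sided_p(beta, se), np.finfo(float).tiny, 1.0
                    ),
                    n=np.full(n_total, n, dtype=np.int64),
                )
            ),
        )

    x_ds = _dataset(x_name, beta_on_x, se_on_x, n_x)
    y_ds = _dataset(y_name, beta_on_y, se_on_y, n_y)
    truth = pd.DataFrame(
        dict(
            snp_id=snp_ids,
            panel=["x"] * jx + ["y"] * jy,
            gamma=np.concatenate([gamma_x, gamma_y]),
            maf=maf,
        )
    )
    return x_ds, y_ds, LDTable(), ConfounderTable(), truth


def simulate_grid(
    exposure_names: list[str],
    outcome_names: list[str],
    beta_matrix,
    n_snps: int = 15,
    n_exposure: int = 10000,
    n_outcome: int = 50000,
    gamma_range: tuple[float, float] = (0.15, 0.3),
    maf_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
) -> tuple[list[GwasDataset], list[GwasDataset], pd.DataFrame]:
    """Exposure x outcome grid with disjoint per-exposure instrument panels.

    ``beta_matrix[e][k]`` is the true causal effect of exposure e on
    outcome k. Each exposure dataset holds its own panel; each outcome
    dataset holds every panel (the realistic shape: an outcome GWAS covers
    all candidate instruments). Outcome effects have no pleiotropy, so any
    signal flows through the configured causal effects only.
    """
    rng = np.random.default_rng(seed)
    beta_matrix = np.atleast_2d(np.asarray(beta_matrix, float))
    n_e, n_o = len(exposure_names), len(outcome_names)
    if beta_matrix.shape != (n_e, n_o):
        raise ValueError("beta_matrix shape must be (n_exposures, n_outcomes)")
    panels = []
    for e in range(n_e):
        ids = np.array([f"rs{e}_{i}" for i in range(n_snps)])
        maf = rng.uniform(*maf_range, size=n_snps)
        gamma = rng.uniform(*gamma_range, size=n_snps) * rng.choice(
            [-1.0, 1.0], size=n_snps
        )
        panels.append((ids, maf, gamma))
    all_ids = np.concatenate([p[0] for p in panels])
    all_maf = np.concatenate([p[1] for p in panels])
    total = len(all_ids)
    chrom = np.array([str(i % 22 + 1) for i in range(total)], dtype=object)
    pos = np.array(
        [1_000_000 + 20_000_000 * (i // 22 + 1) for i in range(total)],
        dtype=np.int64,
    )
    het_x = 2.0 * all_maf * (1.0 - all_maf)
    se_x = (het_x * n_exposure) ** -0.5
    se_y = (het_x * n_outcome) ** -0.5

    def _dataset(name, beta, se, n):
        return GwasDataset(
            trait_name=name,
            records=pd.DataFrame(
                dict(
                    snp_id=all_ids,
                    chrom=chrom,
                    pos=pos,
                    effect_allele=np.array(["A"] * total),
                    other_allele=np.array(["G"] * total),
                    eaf=all_maf,
                    beta=beta,
                    se=se,
                    pval=np.clip(_two_sided_p(beta, se), np.finfo(float).tiny, 1.0),
                    n=np.full(total, n, dtype=np.int64),
                )
            ),
        )

    exposures = []
    for e, name in enumerate(exposure_names):
        # each exposure GWAS: own panel at gamma, other panels null
        mu = np.zeros(total)
        lo = e * n_snps
        mu[lo : lo + n_snps] = panels[e][2]
        beta = rng.normal(mu, se_x)
        ds = _dataset(name, beta, se_x, n_exposure)
        exposures.append(
            GwasDataset(
                name,
                ds.records.iloc[lo : lo + n_snps].reset_index(drop=True),
            )
        )
    outcomes = []
    for k, name in enumerate(outcome_names):
        mu = np.concatenate(
            [beta_matrix[e, k] * panels[e][2] for e in range(n_e)]
        )
        outcomes.append(_dataset(name, rng.normal(mu, se_y), se_y, n_outcome))
    truth = pd.DataFrame(
        dict(
            snp_id=all_ids,
            exposure=np.repeat(exposure_names, n_snps),
            gamma=np.concatenate([p[2] for p in panels]),
            maf=all_maf,
        )
    )
    return exposures, outcomes, truth


def planted_violation_fixture(seed: int = 0):
    """Deterministic fixture with exactly one violation per filter step.

    Returns (exposure, outcome, ld, conf, cross_exposure_context, truth)
    where ``truth`` maps each step (0-5) to the snp_id expected to be
    removed there, plus the surviving set. Five clean SNPs lie exactly on
    the line beta_out = 0.1 * beta_exp, so the MR-PRESSO step flags
    nothing.
    """
    clean_ids = [f"rsclean{i}" for i in range(5)]
    rows = []

    def add(sid, chrom, pos, ea, oa, beta, se, pval, beta_o, se_o, pval_o):
        rows.append(
            dict(snp_id=sid, chrom=chrom, pos=pos, ea=ea, oa=oa,
                 beta=beta, se=se, pval=pval,
                 beta_o=beta_o, se_o=se_o, pval_o=pval_o)
        )

    for i, sid in enumerate(clean_ids):
        add(sid, str(i + 1), 1_000_000, "A", "G",
            0.2, 0.01, 1e-80, 0.02, 0.01, 0.0455)
    # step 0: not significant for the exposure
    add("rsweak", "10", 1_000_000, "A", "G", 0.02, 0.01, 0.5, 0.0, 0.01, 0.9)
    # step 1: in LD (r2=0.5) with the stronger rsclean0, 50 kb away
    add("rsld", "1", 1_050_000, "A", "G", 0.18, 0.01, 1e-60, 0.018, 0.01, 0.07)
    # step 2: also instruments another exposure
    add("rsshared", "11", 1_000_000, "A", "G", 0.2, 0.01, 1e-80, 0.02, 0.01, 0.0455)
    # step 3: annotated to a confounder
    add("rsconf", "12", 1_000_000, "A", "G", 0.2, 0.01, 1e-80, 0.02, 0.01, 0.0455)
    # step 4: palindromic alleles
    add("rspal", "13", 1_000_000, "A", "T", 0.2, 0.01, 1e-80, 0.02, 0.01, 0.0455)
    # step 5: associated with the outcome
    add("rsout", "14", 1_000_000, "A", "G", 0.2, 0.01, 1e-80, 0.05, 0.01, 5.7e-7)

    def _records(side):
        return pd.DataFrame(
            dict(
                snp_id=[r["snp_id"] for r in rows],
                chrom=[r["chrom"] for r in rows],
                pos=[r["pos"] for r in rows],
                effect_allele=[r["ea"] for r in rows],
                other_allele=[r["oa"] for r in rows],
                eaf=0.3,
                beta=[r["beta" if side == "x" else "beta_o"] for r in rows],
                se=[r["se" if side == "x" else "se_o"] for r in rows],
                pval=[r["pval" if side == "x" else "pval_o"] for r in rows],
                n=8293 if side == "x" else 254894,
            )
        )

    exposure = GwasDataset("cytokine", _records("x"))
    outcome = GwasDataset("grip_strength", _records("y"))
    ld = LDTable([("rsclean0", "rsld", 0.5)])
    conf = ConfounderTable({"rsconf": ["BMI"]})
    context = {"other_cytokine": {"rsshared"}}
    truth = {
        "removed_by_step": {
            0: "rsweak",
            1: "rsld",
            2: "rsshared",
            3: "rsconf",
            4: "rspal",
            5: "rsout",
        },
        "final": sorted(clean_ids),
        "seed": seed,
    }
    return exposure, outcome, ld, conf, context, truth


def exact_line_instruments(
    intercept: float = 0.02, slope: float = 0.4
) -> pd.DataFrame:
    """Three instruments exactly on beta_out = intercept + slope*beta_exp."""
    bx = np.array([0.1, 0.2, 0.3])
    return pd.DataFrame(
        dict(
            snp_id=[f"rs{i}" for i in range(3)],
            beta_exp=bx,
            se_exp=0.01,
            beta_out=intercept + slope * bx,
            se_out=0.05,
            eaf_exp=0.3,
            pval_exp=1e-10,
            pval_out=0.5,
            n_exp=8293,
            n_out=254894,
        )
    )


def outlier_fixture(
    n_snps: int = 20, shift_sd: float = 10.0, seed: int = 0
) -> tuple[pd.DataFrame, str]:
    """Null instrument panel with one SNP's outcome effect shifted by
    ``shift_sd`` outcome SEs; returns (instruments, outlier snp_id)."""
    cfg = SimulationConfig(
        n_snps=n_snps,
        n_exposure=10000,
        n_outcome=50000,
        true_beta=0.1,
        prop_invalid=0.0,
        seed=seed,
    )
    exposure, outcome, *_ = simulate_dataset_pair(cfg)
    instruments = instruments_from_truth(exposure, outcome)
    instruments = instruments.reset_index(drop=True)
    instruments.loc[0, "beta_out"] += shift_sd * instruments.loc[0, "se_out"]
    return instruments, str(instruments.loc[0, "snp_id"])


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the named fixtures used across the test-suite to ``out_dir``.

    Each fixture directory holds TSV summary statistics plus a
    ``manifest.json`` truth record (including the generating seed). Returns
    fixture name -> directory path.
    """
    out_dir = Path(out_dir)
    paths: dict[str, Path] = {}

    def _emit(name, datasets, ld=None, conf=None, manifest=None):
        d = out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        for ds in datasets:
            write_summary_stats(ds, d / f"{ds.trait_name}.tsv")
        if ld is not None:
            ld.write_tsv(d / "ld.tsv")
        if conf is not None:
            conf.write_tsv(d / "confounders.tsv")
        manifest = dict(manifest or {})
        manifest.setdefault("seed", seed)
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        paths[name] = d

    exposure, outcome, ld, conf, context, truth = planted_violation_fixture(seed)
    _emit(
        "planted_violations",
        [exposure, outcome],
        ld,
        conf,
        {
            "removed_by_step": {str(k): v for k, v in truth["removed_by_step"].items()},
            "final": truth["final"],
            "cross_exposure_context": {k: sorted(v) for k, v in context.items()},
        },
    )

    instruments, outlier_id = outlier_fixture(seed=seed)
    d = out_dir / "presso_outlier"
    d.mkdir(parents=True, exist_ok=True)
    instruments.to_csv(d / "instruments.tsv", sep="\t", index=False)
    (d / "manifest.json").write_text(
        json.dumps({"outlier": outlier_id, "shift_sd": 10.0, "seed": seed})
    )
    paths["presso_outlier"] = d

    cfg = SimulationConfig(
        n_snps=50,
        n_exposure=10000,
        n_outcome=50000,
        true_beta=0.1,
        prop_invalid=0.3,
        pleiotropy_mean=0.02,
        pleiotropy_sd=0.01,
        seed=seed,
        exposure_name="cytokine_pleio",
        outcome_name="trait_pleio",
    )
    exp_p, out_p, ld_p, conf_p, truth_p = simulate_dataset_pair(cfg)
    _emit(
        "directional_pleiotropy",
        [exp_p, out_p],
        ld_p,
        conf_p,
        {"config": asdict(cfg), "truth": truth_p.to_dict(orient="records")},
    )

    exposures_g, outcomes_g, truth_g = simulate_grid(
        ["cytokineA", "cytokineB"],
        ["traitA", "traitB"],
        [[0.0, 0.0], [0.0, 0.0]],
        seed=seed + 23,
    )
    _emit(
        "null_grid",
        exposures_g + outcomes_g,
        manifest={
            "beta_matrix": [[0.0, 0.0], [0.0, 0.0]],
            "exposures": [d.trait_name for d in exposures_g],
            "outcomes": [d.trait_name for d in outcomes_g],
        },
    )

    d = out_dir / "egger_exact_line"
    d.mkdir(parents=True, exist_ok=True)
    exact_line_instruments().to_csv(d / "instruments.tsv", sep="\t", index=False)
    (d / "manifest.json").write_text(
        json.dumps({"intercept": 0.02, "slope": 0.4, "seed": seed})
    )
    paths["egger_exact_line"] = d
    return paths
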