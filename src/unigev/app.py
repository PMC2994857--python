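"""Pipeline orchestration, configuration, and command-line interface.

Ties the stages together: sequence tabulation -> null-model fit (black-box
Dirichlet or mechanistic polymerase) -> codon partition probabilities ->
per-site Evidence-of-Selection and reliability -> tables, plots, and a run
manifest.  All randomness flows from one master seed through named
substreams, so a rerun with the same configuration is numerically
identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .bayes_multinomial import (
    DEFAULT_ALPHA,
    natural_parameter_matrix,
    relative_frequencies,
    write_frequency_table,
)
from .codon_model import (
    GeneticCode,
    mutation_count_distribution,
    partition_table,
    site_partitions_for_sequence,
)
from .datasets import load_ibmoi_counts
from .pcr_polymerase import (
    ChainSettings,
    DEFAULT_CYCLES,
    map_estimate,
    sample_posterior_T,
)
from .selection_evidence import (
    DEFAULT_ODDS_THRESHOLD,
    EoSResult,
    alternate_hypothesis,
    dirichlet_null_hypothesis,
    eos_score,
    polymerase_null_hypothesis,
    reliability,
)
from .seqdata import (
    ClonePopulation,
    read_fasta_population,
    tabulate_codon_counts,
    tabulate_nucleotide_counts,
    write_codon_counts_tsv,
    write_nucleotide_counts_tsv,
)
from .simulate import SimulationConfig, simulate_clones, write_fasta, write_truth

#: Fixed substream order: every stochastic stage gets a named child seed.
_STREAMS = ("simulate", "mcmc", "eos_us", "eos_mx", "power_us", "power_mx",
            "kappa", "subsample")


@dataclass
class RunConfig:
    """Declarative, fully serializable pipeline configuration."""

    wild_type_fasta: str | None = None
    unselected_fasta: str | None = None
    selected_fasta: str | None = None
    counts_tsv: str | None = None
    alpha: float = DEFAULT_ALPHA
    k_cycles: int = DEFAULT_CYCLES
    null_model: str = "dirichlet"  # "dirichlet" | "polymerase"
    n_mc: int = 10_000
    mcmc_length: int = 50_000
    mcmc_burn_in: int = 5_000
    mcmc_thin: int = 10
    genetic_code_id: int = 1
    eos_threshold_odds: float = DEFAULT_ODDS_THRESHOLD
    stop_policy: str = "nonsynonymous"
    seed: int = 0
    output_dir: str = "unigev_out"
    n_kappa_sim: int = 100_000
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.null_model not in ("dirichlet", "polymerase"):
            raise ValueError(f"unknown null model {self.null_model!r}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def substreams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def eos_table(results: list[EoSResult], threshold_odds: float) -> pd.DataFrame:
    cut = np.log2(threshold_odds)
    rows = [
        {
            "site": r.site_index,
            "population": r.population,
            "R_log2": r.R,
            "mc_se": r.mc_se,
            "D_HA": r.D_HA,
            "D_H0": r.D_H0,
            "n_ns_obs": r.n_ns_observed,
            "n_ns_exp": r.n_ns_expected,
            "selected_flag": bool(r.R >= cut),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _plot_eos(df: pd.DataFrame, threshold_odds: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, df["site"].max() / 8), 4))
    for pop, color in (("mx", "firebrick"), ("us", "steelblue")):
        sub = df[df["population"] == pop]
        ax.bar(sub["site"], sub["R_log2"], color=color, alpha=0.7, label=pop)
    ax.axhline(np.log2(threshold_odds), ls="--", c="k", lw=0.8,
               label=f"{threshold_odds:g}:1 odds")
    ax.set_xlabel("codon site")
    ax.set_ylabel("Evidence of Selection (log2 odds)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_reliability(df: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, pop in zip(axes, ("mx", "us")):
        sub = df[df["population"] == pop]
        ax.bar(sub["site"] - 0.2, sub["D_HA"], width=0.4, color="orchid",
               label="true-pos vs false-neg")
        ax.bar(sub["site"] + 0.2, sub["D_H0"], width=0.4, color="teal",
               label="true-neg vs false-pos")
        ax.set_title(f"population {pop}")
        ax.set_xlabel("codon site")
    axes[0].set_ylabel("expected log2 odds")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _load_populations(cfg: RunConfig) -> tuple[ClonePopulation, ClonePopulation]:
    us = read_fasta_population(cfg.unselected_fasta, cfg.wild_type_fasta, "us")
    mx = read_fasta_population(cfg.selected_fasta, cfg.wild_type_fasta, "mx")
    return us, mx


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest.

    With only a counts TSV (no sequences) the pipeline stops after the
    frequency-estimate report, which is all the counts determine.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = cfg.substreams()
    code = GeneticCode.from_ncbi_id(cfg.genetic_code_id)
    artifacts: list[str] = []

    if cfg.counts_tsv:
        df = pd.read_csv(cfg.counts_tsv, sep="\t", index_col=0)
        from .seqdata import MisincorporationCounts, NUCLEOTIDES

        C_us = MisincorporationCounts(
            df.loc[list(NUCLEOTIDES), list(NUCLEOTIDES)].to_numpy(int), label="us"
        )
        us = mx = None
    else:
        us, mx = _load_populations(cfg)
        C_us = tabulate_nucleotide_counts(us)
        C_mx = tabulate_nucleotide_counts(mx)
        write_nucleotide_counts_tsv([C_us, C_mx], out / "counts_nuc.tsv")
        artifacts.append("counts_nuc.tsv")

    estimates = {
        "Relative Count": relative_frequencies(C_us),
        "Natural Parameter": natural_parameter_matrix(C_us, cfg.alpha),
    }
    fit = None
    chain = None
    if cfg.null_model == "polymerase":
        fit = map_estimate(C_us, cfg.k_cycles)
        estimates["Maximum a posteriori"] = fit.P
        chain = sample_posterior_T(
            C_us,
            cfg.k_cycles,
            ChainSettings(
                length=cfg.mcmc_length,
                burn_in=cfg.mcmc_burn_in,
                thin=cfg.mcmc_thin,
                seed=int(rngs["mcmc"].integers(2**31)),
            ),
            map_fit=fit,
        )
        model_artifact = {
            "T_map": fit.T.T.tolist(),
            "P_map": fit.P.matrix.tolist(),
            "k": cfg.k_cycles,
            "log_posterior": fit.log_posterior,
            "acceptance_rate": chain.acceptance_rate,
            "chain_summary": {
                "draws": int(chain.P_draws.shape[0]),
                "P_posterior_mean": chain.P_draws.mean(axis=0).tolist(),
            },
        }
        with open(out / "polymerase_fit.json", "w") as fh:
            json.dump(model_artifact, fh, indent=1)
        artifacts.append("polymerase_fit.json")
    write_frequency_table(estimates, out / "frequencies.tsv")
    artifacts.append("frequencies.tsv")

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "null_model": cfg.null_model,
        "artifacts": artifacts,
    }

    if us is not None:
        P_point = estimates["Natural Parameter"]
        partitions = site_partitions_for_sequence(us.wild_type, P_point, code)
        ptab = partition_table(partitions, us.n_clones, code)
        ptab.to_csv(out / "site_partitions.tsv", sep="\t", index=False)
        artifacts.append("site_partitions.tsv")

        kappa = mutation_count_distribution(
            partitions, n_sim=cfg.n_kappa_sim, seed=rngs["kappa"]
        )
        pd.DataFrame(
            {"kappa": np.arange(kappa.exact_pmf.size),
             "exact_pmf": kappa.exact_pmf,
             "mc_pmf": np.pad(kappa.pmf, (0, kappa.exact_pmf.size - kappa.pmf.size))}
        ).to_csv(out / "kappa.tsv", sep="\t", index=False)
        artifacts.append("kappa.tsv")

        results: list[EoSResult] = []
        for pop, label in ((us, "us"), (mx, "mx")):
            sites = tabulate_codon_counts(pop, code, cfg.stop_policy)
            write_codon_counts_tsv(sites, code, out / f"counts_codon_{label}.tsv")
            artifacts.append(f"counts_codon_{label}.tsv")
            rng_eos = rngs[f"eos_{label}"]
            rng_pow = rngs[f"power_{label}"]
            for site, part in zip(sites, partitions):
                if cfg.null_model == "polymerase":
                    null = polymerase_null_hypothesis(
                        chain.P_draws, part.wt_codon, code
                    )
                else:
                    null = dirichlet_null_hypothesis(
                        C_us, part.wt_codon, code, cfg.alpha
                    )
                alt = alternate_hypothesis(site, cfg.alpha)
                res = eos_score(site, null, alt, cfg.n_mc, rng_eos, population=label)
                res.D_HA, res.D_H0 = reliability(
                    null, alt, site.n_total or pop.n_clones,
                    n_mc=max(200, cfg.n_mc // 10), seed=rng_pow
                )
                res.n_ns_expected = site.n_total * part.p_ns
                results.append(res)
        df = eos_table(results, cfg.eos_threshold_odds)
        df.to_csv(out / "eos.tsv", sep="\t", index=False)
        artifacts.append("eos.tsv")
        if cfg.make_plots:
            _plot_eos(df, cfg.eos_threshold_odds, out / "eos.png")
            _plot_reliability(df, out / "reliability.png")
            artifacts.extend(["eos.png", "reliability.png"])
        manifest["n_sites"] = len(partitions)
        manifest["n_flagged_mx"] = int(
            df[(df.population == "mx") & df.selected_flag].shape[0]
        )

    manifest["artifacts"] = artifacts
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def subsample_analysis(
    cfg: RunConfig, subset_sizes: list[int], seed: int | None = None
) -> dict[int, pd.DataFrame]:
    """EoS tables for nested (subset-inclusive) clone subsamples.

    Each larger subset contains every clone of the smaller ones, so curves
    across sizes reflect added data rather than resampling noise.
    """
    us, mx = _load_populations(cfg)
    if any(s <= 0 for s in subset_sizes):
        raise ValueError("subset sizes must be positive")
    if max(subset_sizes) > min(us.n_clones, mx.n_clones):
        raise ValueError("subset size exceeds population size")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    order_us = rng.permutation(us.n_clones)
    order_mx = rng.permutation(mx.n_clones)
    out: dict[int, pd.DataFrame] = {}
    base = Path(cfg.output_dir)
    for size in sorted(set(subset_sizes)):
        sub_cfg = RunConfig(**{**asdict(cfg), "output_dir": str(base / f"subsample_{size}")})
        sub_us = ClonePopulation("us", us.wild_type, [us.clones[i] for i in order_us[:size]])
        sub_mx = ClonePopulation("mx", mx.wild_type, [mx.clones[i] for i in order_mx[:size]])
        out[size] = _run_on_populations(sub_cfg, sub_us, sub_mx)
    return out


def _run_on_populations(
    cfg: RunConfig, us: ClonePopulation, mx: ClonePopulation
) -> pd.DataFrame:
    """EoS-only pass over in-memory populations (used by subsampling)."""
    code = GeneticCode.from_ncbi_id(cfg.genetic_code_id)
    rngs = cfg.substreams()
    C_us = tabulate_nucleotide_counts(us)
    P_point = natural_parameter_matrix(C_us, cfg.alpha)
    partitions = site_partitions_for_sequence(us.wild_type, P_point, code)
    results = []
    for pop, label in ((us, "us"), (mx, "mx")):
        sites = tabulate_codon_counts(pop, code, cfg.stop_policy)
        rng_eos = rngs[f"eos_{label}"]
        for site, part in zip(sites, partitions):
            null = dirichlet_null_hypothesis(C_us, part.wt_codon, code, cfg.alpha)
            alt = alternate_hypothesis(site, cfg.alpha)
            res = eos_score(site, null, alt, cfg.n_mc, rng_eos, population=label)
            res.n_ns_expected = site.n_total * part.p_ns
            results.append(res)
    return eos_table(results, cfg.eos_threshold_odds)


# ---------------------------------------------------------------- CLI


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Evidence-of-selection analysis for unigenic evolution experiments."""


_common = [
    click.option("--seed", type=int, default=0, show_default=True),
    click.option("--alpha", type=float, default=DEFAULT_ALPHA, show_default=True),
    click.option("--code", "code_id", type=int, default=1, show_default=True,
                 help="NCBI genetic-code table id"),
    click.option("--out", "output_dir", default="unigev_out", show_default=True),
]


def _add_options(opts):
    def wrap(fn):
        for opt in reversed(opts):
            fn = opt(fn)
        return fn

    return wrap


@cli.command()
@click.option("--wild-type", required=True, type=click.Path(exists=True))
@click.option("--clones", required=True, type=click.Path(exists=True))
@click.option("--label", default="us", show_default=True)
@_add_options(_common)
def counts(wild_type, clones, label, seed, alpha, code_id, output_dir):
    """Tabulate nucleotide and codon mutation counts from FASTA."""
    pop = read_fasta_population(clones, wild_type, label)
    code = GeneticCode.from_ncbi_id(code_id)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    C = tabulate_nucleotide_counts(pop)
    write_nucleotide_counts_tsv([C], out / "counts_nuc.tsv")
    write_codon_counts_tsv(
        tabulate_codon_counts(pop, code), code, out / "counts_codon.tsv"
    )
    click.echo(f"{C.total} events tabulated over {pop.n_clones} clones")


@cli.command("fit-null")
@click.option("--counts-tsv", required=True, type=click.Path(exists=True),
              help="4x4 count matrix TSV (rows=clone nt, cols=wild-type nt)")
@click.option("--model", type=click.Choice(["dirichlet", "polymerase"]),
              default="dirichlet", show_default=True)
@click.option("--cycles", type=int, default=DEFAULT_CYCLES, show_default=True)
@_add_options(_common)
def fit_null(counts_tsv, model, cycles, seed, alpha, code_id, output_dir):
    """Fit a null mutation model and write the frequency report."""
    cfg = RunConfig(counts_tsv=counts_tsv, null_model=model, k_cycles=cycles,
                    alpha=alpha, seed=seed, output_dir=output_dir,
                    genetic_code_id=code_id)
    manifest = run_pipeline(cfg)
    click.echo(json.dumps(manifest, indent=1, sort_keys=True))


@cli.command()
@click.option("--wild-type", required=True, type=click.Path(exists=True))
@click.option("--unselected", required=True, type=click.Path(exists=True))
@click.option("--selected", required=True, type=click.Path(exists=True))
@click.option("--model", type=click.Choice(["dirichlet", "polymerase"]),
              default="dirichlet", show_default=True)
@click.option("--cycles", type=int, default=DEFAULT_CYCLES, show_default=True)
@click.option("--n-mc", type=int, default=10_000, show_default=True)
@click.option("--threshold-odds", type=float, default=DEFAULT_ODDS_THRESHOLD,
              show_default=True)
@_add_options(_common)
def eos(wild_type, unselected, selected, model, cycles, n_mc, threshold_odds,
        seed, alpha, code_id, output_dir):
    """Run the full Evidence-of-Selection pipeline."""
    cfg = RunConfig(
        wild_type_fasta=wild_type, unselected_fasta=unselected,
        selected_fasta=selected, null_model=model, k_cycles=cycles,
        n_mc=n_mc, eos_threshold_odds=threshold_odds, seed=seed, alpha=alpha,
        genetic_code_id=code_id, output_dir=output_dir,
    )
    manifest = run_pipeline(cfg)
    click.echo(f"{manifest.get('n_flagged_mx', 0)} selected-pool sites above "
               f"{threshold_odds:g}:1 odds; outputs in {output_dir}")


@cli.command()
@click.option("--wild-type", required=True, type=click.Path(exists=True))
@click.option("--unselected", required=True, type=click.Path(exists=True))
@click.option("--selected", required=True, type=click.Path(exists=True))
@click.option("--n-mc", type=int, default=2_000, show_default=True)
@_add_options(_common)
def power(wild_type, unselected, selected, n_mc, seed, alpha, code_id, output_dir):
    """Kullback-Leibler reliability (power) estimates per site."""
    cfg = RunConfig(
        wild_type_fasta=wild_type, unselected_fasta=unselected,
        selected_fasta=selected, n_mc=max(n_mc * 10, 1000), seed=seed,
        alpha=alpha, genetic_code_id=code_id, output_dir=output_dir,
        make_plots=True,
    )
    run_pipeline(cfg)
    click.echo(f"reliability columns written to {output_dir}/eos.tsv")


@cli.command()
@click.option("--wild-type", required=True, type=click.Path(exists=True))
@click.option("--counts-tsv", required=True, type=click.Path(exists=True))
@click.option("--n-clones", type=int, default=87, show_default=True)
@click.option("--n-sim", type=int, default=100_000, show_default=True)
@_add_options(_common)
def kappa(wild_type, counts_tsv, n_clones, n_sim, seed, alpha, code_id, output_dir):
    """Whole-protein nonsynonymous mutation-count distribution."""
    from .seqdata import MisincorporationCounts, NUCLEOTIDES
    from Bio import SeqIO

    df = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    C = MisincorporationCounts(
        df.loc[list(NUCLEOTIDES), list(NUCLEOTIDES)].to_numpy(int)
    )
    wt = str(next(SeqIO.parse(wild_type, "fasta")).seq).upper()
    code = GeneticCode.from_ncbi_id(code_id)
    P = natural_parameter_matrix(C, alpha)
    partitions = site_partitions_for_sequence(wt, P, code)
    dist = mutation_count_distribution(partitions, n_sim=n_sim, seed=seed)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"kappa": np.arange(dist.exact_pmf.size),
                  "exact_pmf": dist.exact_pmf,
                  "mc_pmf": np.pad(dist.pmf, (0, dist.exact_pmf.size - dist.pmf.size)),
                  }).to_csv(out / "kappa.tsv", sep="\t", index=False)
    click.echo(f"kappa distribution written to {out / 'kappa.tsv'}")


@cli.command("simulate")
@click.option("--n-codons", type=int, default=266, show_default=True)
@click.option("--n-clones", type=int, default=87, show_default=True)
@click.option("--selected-sites", default="", help="comma-separated 1-based codon sites")
@click.option("--use-example-rates/--uniform-rates", default=True, show_default=True,
              help="derive the mutation matrix from the packaged example counts")
@_add_options(_common)
def simulate_cmd(n_codons, n_clones, selected_sites, use_example_rates,
                 seed, alpha, code_id, output_dir):
    """Generate a synthetic experiment with known ground truth."""
    sites = frozenset(int(s) for s in selected_sites.split(",") if s.strip())
    if use_example_rates:
        P = natural_parameter_matrix(load_ibmoi_counts("unselected"), alpha)
    else:
        P = np.full((4, 4), 0.005) + np.eye(4) * (1 - 0.02)
    cfg = SimulationConfig(
        n_codons=n_codons, n_clones=n_clones, P=P,
        selected_sites=sites, seed=seed,
        code=GeneticCode.from_ncbi_id(code_id),
    )
    us, mx, truth = simulate_clones(cfg)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "wild_type.fasta", "w") as fh:
        fh.write(f">wild_type\n{us.wild_type}\n")
    write_fasta(us, out / "unselected.fasta")
    write_fasta(mx, out / "selected.fasta")
    write_truth(truth, out / "truth.json")
    click.echo(f"simulated {n_clones}+{n_clones} clones over {n_codons} codons")


@cli.command()
@click.option("--wild-type", required=True, type=click.Path(exists=True))
@click.option("--unselected", required=True, type=click.Path(exists=True))
@click.option("--selected", required=True, type=click.Path(exists=True))
@click.option("--sizes", required=True, help="comma-separated subset sizes")
@_add_options(_common)
def subsample(wild_type, unselected, selected, sizes, seed, alpha, code_id,
              output_dir):
    """Nested clone-subsample sensitivity analysis."""
    cfg = RunConfig(
        wild_type_fasta=wild_type, unselected_fasta=unselected,
        selected_fasta=selected, seed=seed, alpha=alpha,
        genetic_code_id=code_id, output_dir=output_dir, n_mc=2000,
    )
    size_list = [int(s) for s in sizes.split(",")]
    tables = subsample_analysis(cfg, size_list)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for size, df in tables.items():
        df.to_csv(out / f"eos_subsample_{size}.tsv", sep="\t", index=False)
    click.echo(f"subsample tables for sizes {sorted(tables)} in {output_dir}")


@cli.command()
@click.option("--out", "output_dir", default="unigev_out", show_default=True)
def report(output_dir):
    """Summarize an existing output directory."""
    out = Path(output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise click.ClickException(f"no manifest in {output_dir}")
    manifest = json.loads(manifest_path.read_text())
    click.echo(json.dumps(manifest, indent=1, sort_keys=True))


def main() -> None:  # pragma: no cover
    try:
        cli(standalone_mode=False)
    except (ValueError, FileNotFoundError) as exc:
        click.echo(f"data error: {exc}", err=True)
        raise SystemExit(1)
    except (FloatingPointError, np.linalg.LinAlgError, RuntimeError) as exc:
        click.echo(f"numerical failure: {exc}", err=True)
        raise SystemExit(2)
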