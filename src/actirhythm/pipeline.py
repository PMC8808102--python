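"""End-to-end orchestration: cohort → PDFs → Jaccard curve → spectra → KS table.

One :class:`RunConfig` drives the whole analysis from either a synthetic
cohort (seeded, reproducible) or an on-disk cohort table.  Every stage
writes its artifact as tabular text so stages are individually
re-loadable; a machine-readable ``summary.json`` collects the headline
quantities (τ_min in minutes, plateau bounds/width, per-component
significance labels).  All analysis stages are deterministic; the master
seed governs simulation only, so identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import groupstats, io, jaccard, profiles, spectral
from .synthetic import SyntheticConfig, config_from_dict, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input mode is set."""

    synthetic: SyntheticConfig | None = None
    cohort_path: str | None = None
    output_dir: str = "actirhythm_run"
    K: int = spectral.DEFAULT_K
    plateau_tol: float = jaccard.DEFAULT_PLATEAU_TOL
    sig_threshold: float = groupstats.SIG_THRESHOLD
    marginal_threshold: float = groupstats.MARGINAL_THRESHOLD
    seed: int | None = None
    make_figures: bool = False

    def validate(self) -> None:
        if (self.synthetic is None) == (self.cohort_path is None):
            raise ValueError(
                "exactly one input mode must be set: synthetic config or cohort_path"
            )


@dataclass
class RunReport:
    """Artifact paths plus the headline summary of one run."""

    output_dir: Path
    artifacts: dict[str, Path]
    summary: dict


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; on any stage error remove partial outputs."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "cohort"
        if config.synthetic is not None:
            syn = config.synthetic
            if config.seed is not None:
                syn = dataclasses.replace(syn, seed=config.seed)
            recordings = simulate_cohort(syn)
            artifacts["cohort"] = outdir / "cohort.csv"
            io.write_cohort(recordings, artifacts["cohort"])
        else:
            recordings = io.read_cohort(config.cohort_path)
        matrices = io.cohort_day_matrices(recordings)
        groups = sorted({m.group for m in matrices})
        if len(groups) != 2:
            raise ValueError(f"need exactly two groups, found {groups}")

        stage = "pdfs"
        group_pdfs = profiles.group_profiles(matrices)
        for g, pdf in group_pdfs.items():
            artifacts[f"pdf_{g}"] = outdir / f"pdf_{g}.tsv"
            profiles.write_pdf(pdf, artifacts[f"pdf_{g}"])

        stage = "jaccard"
        epoch_minutes = matrices[0].epoch_minutes
        curve = jaccard.delayed_jaccard(
            group_pdfs[groups[0]],
            group_pdfs[groups[1]],
            plateau_tol=config.plateau_tol,
            epoch_minutes=epoch_minutes,
        )
        artifacts["jaccard_curve"] = outdir / "jaccard_curve.tsv"
        jaccard.write_curve(curve, artifacts["jaccard_curve"])

        stage = "spectra"
        ensembles = spectral.build_ensembles(matrices, K=config.K)
        artifacts["ensembles"] = outdir / "ensembles.tsv"
        spectral.write_ensembles(ensembles, artifacts["ensembles"])
        artifacts["spectral_summary"] = outdir / "spectral_summary.tsv"
        spectral.ensemble_summary(ensembles).to_csv(
            artifacts["spectral_summary"], sep="\t", index=False
        )

        stage = "ks_tests"
        results = groupstats.componentwise_tests(
            ensembles[groups[0]],
            ensembles[groups[1]],
            K=config.K,
            sig_threshold=config.sig_threshold,
            marginal_threshold=config.marginal_threshold,
        )
        artifacts["ks_table"] = outdir / "ks_table.tsv"
        groupstats.write_results(results, artifacts["ks_table"])

        if config.make_figures:
            stage = "figures"
            _make_figures(outdir, group_pdfs, curve, ensembles, artifacts)

        stage = "summary"
        summary = {
            "groups": groups,
            "n_subjects": {
                g: sum(1 for m in matrices if m.group == g) for g in groups
            },
            "n_day_segments": {
                g: sum(m.n_days for m in matrices if m.group == g) for g in groups
            },
            "epoch_minutes": epoch_minutes,
            "day_length": matrices[0].day_length,
            "tau_min_epochs": curve.tau_min,
            "tau_min_minutes": curve.tau_min_minutes,
            "jaccard_at_min": curve.min_value,
            "plateau": list(curve.plateau),
            "plateau_width_minutes": curve.plateau_width_minutes,
            "significant_phase_components": [
                r.k for r in results if r.label_phase == "significant"
            ],
            "marginal_amplitude_components": [
                r.k for r in results if r.label_amplitude == "marginal"
            ],
            "component_labels": {
                str(r.k): {"amplitude": r.label_amplitude, "phase": r.label_phase}
                for r in results
            },
        }
        artifacts["summary"] = outdir / "summary.json"
        artifacts["summary"].write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    except Exception as exc:
        for path in artifacts.values():
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    logger.info("pipeline complete; artifacts in %s", outdir)
    return RunReport(output_dir=outdir, artifacts=artifacts, summary=summary)


def _make_figures(outdir, group_pdfs, curve, ensembles, artifacts) -> None:
    # figures mirror the two canonical views: group PDFs with the delayed
    # Jaccard curve, and per-component spectral summaries
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for g, pdf in group_pdfs.items():
        axes[0].plot(np.arange(pdf.l), pdf.values, label=g)
    axes[0].set(xlabel="epoch of day", ylabel="motion probability", title="group PDFs")
    axes[0].legend()
    axes[1].plot(curve.taus, curve.values)
    axes[1].axvline(curve.tau_min, color="r", ls="--",
                    label=f"tau_min={curve.tau_min_minutes:g} min")
    axes[1].set(xlabel="shift tau (epochs)", ylabel="J(tau)",
                title="delayed Jaccard distance")
    axes[1].legend()
    fig.tight_layout()
    artifacts["figure_profiles"] = outdir / "profiles.png"
    fig.savefig(artifacts["figure_profiles"], dpi=120)
    plt.close(fig)

    summary = spectral.ensemble_summary(ensembles)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for g, sub in summary.groupby("group"):
        axes[0].loglog(sub["k"], sub["mean_amplitude"], label=g)
        axes[1].semilogx(sub["k"], sub["mean_phase_radians"], "o", label=g)
    axes[0].set(xlabel="component k", ylabel="mean amplitude")
    axes[1].set(xlabel="component k", ylabel="mean phase (rad)")
    for ax in axes:
        ax.legend()
    fig.tight_layout()
    artifacts["figure_spectra"] = outdir / "spectra.png"
    fig.savefig(artifacts["figure_spectra"], dpi=120)
    plt.close(fig)


def run_config_from_yaml(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; the ``synthetic`` key holds a cohort config."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "synthetic" in doc and doc["synthetic"] is not None:
        doc["synthetic"] = config_from_dict(doc["synthetic"])
    config = RunConfig(**doc)
    config.validate()
    return config
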