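"""End-to-end orchestration of the two-state footprinting comparison.

The pipeline chains the stages the library exposes individually:
candidate enumeration → MS1 peptide-mass matching → MS/MS site
localization → per-state accessibility maps → differential report with
domain annotation.  Inputs are either measured peak lists or a synthetic
experiment; every run can write its match/localization tables, the report,
and a manifest recording parameters, seed and content checksums so a rerun
from the same manifest is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .digest import PeptideForm, ProteinRecord, enumerate_modforms
from .footprint_compare import (
    DEFAULT_DOMAINS,
    AccessibilityMap,
    DifferentialReport,
    DomainTable,
    annotate_domains,
    build_accessibility_map,
    compare_states,
)
from .io_formats import PeakList, write_report
from .masses import BIOTIN_LC, ModificationDef, mz_from_mass
from .pmf_match import PmfResult, match_pmf
from .site_localization import (
    CONFIDENT_DELTA_ASCORE,
    DEFAULT_FRAGMENT_TOL_DA,
    SiteLocalizationResult,
    ascore,
)
from .synthetic_data import (
    RecoveryMetrics,
    SimulatedExperiment,
    SyntheticConfig,
    evaluate_recovery,
    simulate_experiment,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a footprinting comparison run needs.

    Provide either a ``synthetic`` config (the experiment is simulated) or
    a protein plus per-state MS1/MS2 peak lists.
    """

    synthetic: SyntheticConfig | None = None
    protein: ProteinRecord | None = None
    ms1: Mapping[str, PeakList] | None = None
    ms2: Mapping[str, Sequence[PeakList]] | None = None
    mod: ModificationDef = BIOTIN_LC
    tol_ppm: float = 50.0
    fragment_tol_da: float = DEFAULT_FRAGMENT_TOL_DA
    min_delta_ascore: float = CONFIDENT_DELTA_ASCORE
    min_witnesses: int = 1
    max_missed: int = 2
    max_var_mods_per_peptide: int = 6
    domains: DomainTable = DEFAULT_DOMAINS
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and (
            self.protein is None or self.ms1 is None or self.ms2 is None
        ):
            raise ValueError(
                "provide either a synthetic config or protein + ms1 + ms2"
            )
        if self.min_witnesses < 1:
            raise ValueError("min_witnesses must be >= 1")


@dataclass(frozen=True)
class PipelineResult:
    report: DifferentialReport
    maps: Mapping[str, AccessibilityMap]
    pmf: Mapping[str, PmfResult]
    localizations: Mapping[str, tuple[SiteLocalizationResult, ...]]
    recovery: RecoveryMetrics | None = None
    manifest: dict = field(default_factory=dict)


def candidate_sites_for(form: PeptideForm, mod: ModificationDef) -> list[int]:
    """Positions in the peptide that could carry the modification (the
    C-terminal residue is excluded: a blocked site cannot have been cut)."""
    return [
        p
        for p in range(form.start, form.end)
        if form.sequence[p - form.start] in mod.targets
    ]


def localize_state(
    assignments: Sequence,
    ms2_spectra: Sequence[PeakList],
    mod: ModificationDef = BIOTIN_LC,
    fragment_tol_da: float = DEFAULT_FRAGMENT_TOL_DA,
    precursor_tol_da: float = 0.2,
) -> list[SiteLocalizationResult]:
    """Run site localization for every MS2 spectrum that links (by
    precursor m/z) to an assigned label-bearing peptide."""
    modified_matches = [
        m
        for m in assignments
        if any(md.name == mod.name for _, md in m.peptide.mods)
    ]
    results = []
    for spectrum in ms2_spectra:
        if spectrum.precursor_mz is None:
            continue
        linked = [
            m
            for m in modified_matches
            if abs(
                mz_from_mass(m.peptide.mass(), 1) - spectrum.precursor_mz
            )
            <= precursor_tol_da
        ]
        if not linked:
            continue
        match = min(
            linked,
            key=lambda m: abs(
                mz_from_mass(m.peptide.mass(), 1) - spectrum.precursor_mz
            ),
        )
        form = match.peptide
        n_mod = sum(1 for _, md in form.mods if md.name == mod.name)
        sites = candidate_sites_for(form, mod)
        if n_mod == 1:
            results.append(
                ascore(
                    spectrum,
                    form,
                    sites,
                    mod=mod,
                    window_tol_da=fragment_tol_da,
                )
            )
        elif n_mod == len(sites):
            # every candidate residue is labeled: each site is unambiguous
            for site in sites:
                results.append(
                    ascore(spectrum, form, [site], mod=mod,
                           window_tol_da=fragment_tol_da)
                )
        else:
            logger.debug(
                "skipping %s: %d labels over %d candidate sites",
                form.sequence, n_mod, len(sites),
            )
    return results


def _localization_records(
    localizations: Sequence[SiteLocalizationResult],
) -> list[dict]:
    return [
        {
            "sequence": loc.peptide.sequence,
            "start": loc.peptide.start,
            "end": loc.peptide.end,
            "candidate_sites": ";".join(map(str, loc.candidate_sites)),
            "best_site": loc.best_site,
            "delta_ascore": loc.delta_ascore,
            "verdict": "confident" if loc.is_confident() else "ambiguous",
        }
        for loc in localizations
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_footprint_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full comparison and (optionally) write artifacts."""
    recovery = None
    if config.synthetic is not None:
        experiment: SimulatedExperiment = simulate_experiment(config.synthetic)
        protein = experiment.protein
        ms1, ms2 = experiment.ms1, experiment.ms2
    else:
        protein, ms1, ms2 = config.protein, config.ms1, config.ms2

    states = list(ms1)
    if len(states) != 2:
        raise ValueError(f"expected exactly two states, got {states}")

    logger.info("enumerating candidate forms for %s (%d aa)", protein.id, len(protein))
    candidates = enumerate_modforms(
        protein,
        variable_mods=[config.mod],
        max_missed=config.max_missed,
        max_var_mods_per_peptide=config.max_var_mods_per_peptide,
    )
    logger.info("%d candidate peptide forms", len(candidates))

    pmf: dict[str, PmfResult] = {}
    localizations: dict[str, tuple[SiteLocalizationResult, ...]] = {}
    maps: dict[str, AccessibilityMap] = {}
    for state in states:
        result = match_pmf(
            candidates, ms1[state], tol_ppm=config.tol_ppm, charge_states=(1,)
        )
        pmf[state] = result
        locs = localize_state(
            result.assignments,
            ms2.get(state, ()),
            mod=config.mod,
            fragment_tol_da=config.fragment_tol_da,
        )
        localizations[state] = tuple(locs)
        maps[state] = build_accessibility_map(
            state,
            result.assignments,
            locs,
            min_delta_ascore=config.min_delta_ascore,
            min_witnesses=config.min_witnesses,
            protein=protein,
        )
        logger.info(
            "state %s: %d MS1 assignments, %d localizations, %d lysines called",
            state, len(result.assignments), len(locs), len(maps[state].positions),
        )

    report = annotate_domains(
        compare_states(maps[states[0]], maps[states[1]]), config.domains
    )
    if config.synthetic is not None:
        recovery = evaluate_recovery(experiment.truth, report, maps)

    manifest: dict = {
        "protein_id": protein.id,
        "states": states,
        "parameters": {
            "tol_ppm": config.tol_ppm,
            "fragment_tol_da": config.fragment_tol_da,
            "min_delta_ascore": config.min_delta_ascore,
            "min_witnesses": config.min_witnesses,
            "max_missed": config.max_missed,
            "max_var_mods_per_peptide": config.max_var_mods_per_peptide,
            "mod": config.mod.name,
        },
        "seed": config.synthetic.seed if config.synthetic else None,
        "outputs": {},
    }

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for state in states:
            match_path = outdir / f"matches_{state}.tsv"
            pd.DataFrame.from_records(pmf[state].to_records()).to_csv(
                match_path, sep="\t", index=False
            )
            loc_path = outdir / f"localizations_{state}.tsv"
            pd.DataFrame.from_records(
                _localization_records(localizations[state])
            ).to_csv(loc_path, sep="\t", index=False)
            manifest["outputs"][match_path.name] = _sha256(match_path)
            manifest["outputs"][loc_path.name] = _sha256(loc_path)
        for fmt in ("tsv", "json"):
            report_path = outdir / f"differential_report.{fmt}"
            write_report(report, report_path, format=fmt)
            manifest["outputs"][report_path.name] = _sha256(report_path)
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")

    return PipelineResult(
        report=report,
        maps=maps,
        pmf=pmf,
        localizations=localizations,
        recovery=recovery,
        manifest=manifest,
    )
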