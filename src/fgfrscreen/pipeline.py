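"""End-to-end orchestration: simulate → screen → dose-response panel."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .drug_response import PanelReport, analyze_panel
from .io import plates_from_frame, records_from_frame
from .simulate import (
    ScenarioBundle,
    SimulatedCalls,
    SimulatedPlates,
    scenario_study,
    simulate_callsets,
    simulate_plates,
)
from .variants import ScreenReport, screen_cohort

__all__ = ["ScenarioResult", "run_variant_stage", "run_plate_stage", "run_study_scenario"]


@dataclass
class ScenarioResult:
    bundle: ScenarioBundle
    calls: SimulatedCalls
    screen: ScreenReport
    plates: SimulatedPlates
    panel: PanelReport

    def summary_dict(self) -> dict:
        """Headline numbers of both stages, JSON-ready."""
        by_cohort = {
            row["cohort"]: {
                "n_samples": int(row["n_samples"]),
                "surviving_variants": int(row["surviving_variants"]),
                "frequency": float(row["frequency"]),
            }
            for _, row in self.screen.summary.iterrows()
        }
        survivors = self.screen.survivors
        wil = self.panel.wilcoxon_by_replicate
        return {
            "variant_stage": {
                "cohorts": by_cohort,
                "survivors": [
                    {
                        "sample": r["sample"],
                        "gene": r["gene"],
                        "protein_change": r["protein_change"],
                        "domain": r["domain"],
                        "hotspot": bool(r["hotspot"]),
                        "vaf": float(r["vaf"]),
                    }
                    for _, r in survivors.iterrows()
                ],
            },
            "drug_response_stage": {
                "n_responsive": self.panel.n_responsive,
                "mean_fold_responsive": self.panel.mean_fold_responsive,
                "n_reversed": int(self.panel.lines["reversed"].sum()),
                "wilcoxon_p_by_replicate": wil.p_two_sided if wil else None,
                "wilcoxon_method": wil.method if wil else None,
            },
        }


def run_variant_stage(bundle: ScenarioBundle, seed: Optional[int] = None):
    """Simulate the call sets of a scenario and run the full screen."""
    calls = simulate_callsets(bundle.call_config)
    report = screen_cohort(
        records_from_frame(calls.calls),
        calls.manifest,
        list(bundle.models.values()),
        bundle.snp_list,
        bundle.domains,
        bundle.hotspots,
        cfg=bundle.filter_config,
        targets=bundle.targets,
        seed=bundle.call_config.seed if seed is None else seed,
    )
    return calls, report


def run_plate_stage(bundle: ScenarioBundle) -> tuple[SimulatedPlates, PanelReport]:
    plates = simulate_plates(bundle.plate_config)
    panel = analyze_panel(plates_from_frame(plates.plates))
    return plates, panel


def run_study_scenario(seed: int = 17) -> ScenarioResult:
    """Run the packaged worked-example scenario end to end."""
    bundle = scenario_study(seed)
    calls, screen = run_variant_stage(bundle)
    plates, panel = run_plate_stage(bundle)
    return ScenarioResult(bundle=bundle, calls=calls, screen=screen, plates=plates, panel=panel)
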