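"""Shared fixtures: small synthetic study systems and reference objects."""

import numpy as np
import pandas as pd
import pytest

from mameta.simulate import (
    SimulationConfig,
    simulate_haplotype_panels,
    simulate_study_summaries,
)

# three clusters whose profiles differ by 4 z-units on several phenotypes,
# mimicking opposed sign patterns of cardiometabolic trait effects
SIGN_CENTROIDS = 2.0 * np.array(
    [
        [1, 1, 1, 0, 0, -1, -1, 0, 1, -1],
        [-1, 0, 1, 1, -1, 1, 0, -1, 0, 1],
        [0, -1, -1, 1, 1, 0, 1, 1, -1, 0],
    ],
    dtype=float,
)


@pytest.fixture(scope="session")
def base_config():
    return SimulationConfig(
        n_snvs=300,
        seed=11,
        group_fst={"AFR": 0.12, "EAS": 0.08, "EUR": 0.05},
    )


@pytest.fixture(scope="session")
def panels(base_config):
    return simulate_haplotype_panels(base_config)


@pytest.fixture(scope="session")
def studies_null(base_config, panels):
    """Twelve studies with no planted effects."""
    studies, truth = simulate_study_summaries(base_config, panels)
    return studies, truth


def make_studies(snv_effects: dict[str, dict], n_studies: int = 6) -> list:
    """Hand-built StudySummary list from per-study SNV tables.

    ``snv_effects`` maps study id -> dict with keys SNV, EA, NEA, EAF,
    BETA, SE (parallel lists).
    """
    from mameta.simulate import StudySummary

    out = []
    for sid, cols in snv_effects.items():
        t = pd.DataFrame(cols)
        t["CHR"] = t.get("CHR", 1)
        t["POS"] = t.get("POS", range(1, len(t) + 1))
        t["INFO"] = 1.0
        out.append(
            StudySummary(
                study_id=sid,
                ancestry="EUR",
                table=t,
                n_cases=5000,
                n_controls=5000,
                mean_bmi_cases=30.0,
                mean_bmi_controls=27.0,
            )
        )
    return out


class DictLD:
    """LD stub answering max-over-groups r^2 from a dictionary."""

    def __init__(self, r2_map: dict, default: float = 0.0,
                 groups: tuple[str, ...] = ("g1",)):
        self.r2_map = {frozenset(k): v for k, v in r2_map.items()}
        self.default = default
        self.groups = groups

    def max_r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        v = self.r2_map.get(frozenset((a, b)), self.default)
        return max(v.values()) if isinstance(v, dict) else v

    def r2(self, a: str, b: str):
        if a == b:
            per = {g: 1.0 for g in self.groups}
            return per, 1.0
        v = self.r2_map.get(frozenset((a, b)), self.default)
        if isinstance(v, dict):
            return v, max(v.values())
        per = {g: v for g in self.groups}
        return per, v
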