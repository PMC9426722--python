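import dataclasses

import pytest

from gastrokin import GroundTruth, StudyDesign, default_ground_truth


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return default_ground_truth()


@pytest.fixture(scope="session")
def noise_free_truth(truth) -> GroundTruth:
    """Generator truth with all noise and between-subject variation removed."""
    measures = {
        name: dataclasses.replace(
            mt, noise_sd=0.0, cv={k: 0.0 for k in mt.cv}
        )
        for name, mt in truth.measures.items()
    }
    return GroundTruth(measures)


@pytest.fixture
def default_design() -> StudyDesign:
    return StudyDesign(seed=1)


def single_arm_design(n: int, seed: int, arm: str = "PS-LE1") -> StudyDesign:
    """A one-arm mini-study used by recovery and calibration replicates."""
    return StudyDesign(
        n_recruited=n,
        arms=(arm,),
        arms_per_subject=1,
        final_n=(n,),
        seed=seed,
        missing_rate=0.0,
    )
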