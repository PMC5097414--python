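import pytest

from harmsynth.data_model import (
    ArmSummaryBinary,
    ClassificationScheme,
    StudyRecord,
    TrialSet,
    TwoByTwoTable,
)
from harmsynth.simulate import make_paper_fixture


def make_binary_study(study_id, r_t, n_t, r_c, n_c, blinded=True, year=None):
    return StudyRecord(
        study_id=study_id,
        year=year,
        blinded=blinded,
        binary=(
            ArmSummaryBinary("treatment", n_t, r_t),
            ArmSummaryBinary("control", n_c, r_c),
        ),
    )


@pytest.fixture(scope="session")
def fixture_sets():
    """Margin-matched synthetic SAE/NSAE trial sets and the scenario ladder."""
    return make_paper_fixture()


@pytest.fixture(scope="session")
def sae_trials(fixture_sets):
    return fixture_sets[0]


@pytest.fixture(scope="session")
def nsae_trials(fixture_sets):
    return fixture_sets[1]


@pytest.fixture(scope="session")
def scenarios(fixture_sets):
    return fixture_sets[2]


@pytest.fixture
def team_scheme():
    """Clinical-judgment style scheme: sprain non-serious, cancer not an AE."""
    return ClassificationScheme(
        name="team_judgment",
        rules={
            "joint sprain": ("non_serious", "joint"),
            "cancer": ("not_an_AE", "n/a"),
            "synovitis": ("serious", "joint"),
            "herpes zoster": ("serious", "other"),
            "headache": ("non_serious", "other"),
            "erythema": ("non_serious", "local_non_joint"),
            "pain": ("non_serious", "joint"),
        },
        fallback="use_author_flag",
    )


@pytest.fixture
def author_scheme():
    """Author-designation style scheme: defers to the original trial labels."""
    return ClassificationScheme(
        name="author_designation",
        rules={
            "joint sprain": ("serious", "joint"),
            "cancer": ("serious", "other"),
            "synovitis": ("serious", "joint"),
            "headache": ("non_serious", "other"),
        },
        fallback="use_author_flag",
    )
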