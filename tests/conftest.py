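import pytest

from cardiotrans.models import DrugStudy


@pytest.fixture(scope="session")
def desk_study() -> DrugStudy:
    """Shared desk-scale study (cached baseline limit cycles)."""
    study = DrugStudy.desk()
    study.baseline_biomarkers("rat")
    study.baseline_biomarkers("human")
    return study


@pytest.fixture(scope="session")
def rat_baseline(desk_study):
    return desk_study.baseline("rat")


@pytest.fixture(scope="session")
def human_baseline(desk_study):
    return desk_study.baseline("human")
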