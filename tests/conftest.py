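import pytest

from autova import (
    CauseList,
    SymptomSchema,
    TariffModel,
    TariffOptions,
    TrainingDeath,
    TrainingLibrary,
)

SYMPTOMS = ("s01", "s02", "s03", "s04", "s05", "s06", "s07", "s08", "s09", "s10")
CAUSES = ("cause_a", "cause_b", "cause_c", "cause_d", "cause_e")


@pytest.fixture
def adult_schema() -> SymptomSchema:
    return SymptomSchema(module_id="adult", symptoms=SYMPTOMS)


@pytest.fixture
def cause_list() -> CauseList:
    return CauseList(causes=CAUSES)


def make_training(schema, causes, pattern) -> TrainingLibrary:
    """Build a library from {cause: [endorsement tuple per death]}."""
    deaths = []
    for cause in causes.causes:
        for k, bits in enumerate(pattern[cause]):
            deaths.append(
                TrainingDeath(
                    death_id=f"{cause}-{k}",
                    cause=cause,
                    endorsements=dict(zip(schema.symptoms, bits)),
                )
            )
    return TrainingLibrary(module_id=schema.module_id, deaths=deaths)


@pytest.fixture
def tiny_training(adult_schema, cause_list) -> TrainingLibrary:
    """Each cause endorses two signature symptoms; deterministic, 4 deaths/cause."""
    pattern = {}
    for j, cause in enumerate(cause_list.causes):
        bits = [0] * len(SYMPTOMS)
        bits[2 * j] = 1
        bits[2 * j + 1] = 1
        # three identical deaths plus one with a flipped background symptom
        noisy = list(bits)
        noisy[(2 * j + 3) % len(SYMPTOMS)] = 1
        pattern[cause] = [tuple(bits)] * 3 + [tuple(noisy)]
    return make_training(adult_schema, cause_list, pattern)


@pytest.fixture
def tiny_model(tiny_training, cause_list, adult_schema) -> TariffModel:
    return TariffModel.train(
        tiny_training,
        cause_list,
        adult_schema,
        options=TariffOptions(truncate_top_k=None),
        per_cause_n=20,
        seed=11,
    )
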