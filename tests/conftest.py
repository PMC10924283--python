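import pytest
from hypothesis import HealthCheck, settings

import groundling as g
from groundling.fixtures import packaged_lexicon

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

WORKED_TEXT = "garlic powder (2 tablespoons)"
WORKED_PAYLOAD = "food_item: garlic powder\namount: 2 tablespoons"
QUANTITY_PAYLOAD = "value: 2\nunit: tablespoons"


@pytest.fixture(scope="session")
def recipe_schema():
    return g.recipe_schema()


@pytest.fixture(scope="session")
def ctd_schema():
    return g.ctd_schema()


@pytest.fixture(scope="session")
def recipe_lexicon():
    return packaged_lexicon("recipe_lexicon.tsv")


@pytest.fixture()
def worked_backend(recipe_schema):
    """A mock backend pre-loaded with the garlic-powder worked example."""
    prompts = {
        g.generate_prompt(recipe_schema, "Ingredient", WORKED_TEXT): WORKED_PAYLOAD,
        g.generate_prompt(recipe_schema, "Quantity", "2 tablespoons"): QUANTITY_PAYLOAD,
    }
    return g.MockBackend(prompts)


@pytest.fixture()
def worked_grounder(recipe_lexicon):
    return g.Grounder(lexicons=[recipe_lexicon])
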