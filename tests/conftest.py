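import pytest

from strokecea import fixtures


@pytest.fixture(scope="session")
def base_spec():
    """Trial-anchored base-case model; treat as read-only (copy to mutate)."""
    return fixtures.paper_base_fixture()


@pytest.fixture(scope="session")
def base_result(base_spec):
    from strokecea import economics

    return economics.compare_arms(base_spec)


MINIMAL_DOC = """
arms:
  - name: control
    dose_per_kg: 0.9
    flat_drug_cost: 100
    dist90: {mRS01: 0.2, mRS23: 0.2, mRS4: 0.2, mRS5: 0.2, dead: 0.2}
  - name: treatment
    dose_per_kg: 0.25
    flat_drug_cost: 120
    dist90: {mRS01: 0.2, mRS23: 0.2, mRS4: 0.2, mRS5: 0.2, dead: 0.2}
t_90to1:
  mRS01: [0.2, 0.2, 0.2, 0.2, 0.2]
  mRS23: [0.2, 0.2, 0.2, 0.2, 0.2]
  mRS4: [0.2, 0.2, 0.2, 0.2, 0.2]
  mRS5: [0.2, 0.2, 0.2, 0.2, 0.2]
  dead: [0, 0, 0, 0, 1]
t_annual:
  mRS01: [0.2, 0.2, 0.2, 0.2, 0.2]
  mRS23: [0.2, 0.2, 0.2, 0.2, 0.2]
  mRS4: [0.2, 0.2, 0.2, 0.2, 0.2]
  mRS5: [0.2, 0.2, 0.2, 0.2, 0.2]
  dead: [0, 0, 0, 0, 1]
utilities: {mRS01: 0.8, mRS23: 0.6, mRS4: 0.4, mRS5: 0.2, dead: 0}
annual_costs: {mRS01: 1000, mRS23: 2000, mRS4: 3000, mRS5: 4000, dead: 0}
patient: {start_age: 70, weight: 75}
life_table: {70: 0.02}
"""


@pytest.fixture()
def minimal_doc():
    return MINIMAL_DOC
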