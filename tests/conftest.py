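import pytest

from prevfrac import table1


@pytest.fixture(scope="session")
def trial_spec():
    """The packaged six-cell hypothetical-trial scenario."""
    return table1()


# exact (unrounded) population values of the packaged trial scenario
TRIAL_P_Y1 = 0.303
TRIAL_P_CF1 = 0.234
TRIAL_PF_TOTAL = 0.069 / 0.303
TRIAL_WEIGHTS = {"0": 0.200 / 0.303, "1": 0.075 / 0.303, "2": 0.028 / 0.303}
TRIAL_PF_M = {"0": 0.25, "1": 0.20, "2": 0.02 / 0.14}
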