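import numpy as np
import pytest

from chromlgn import stimdesign as sd


@pytest.fixture(scope="session")
def primaries():
    return sd.default_primaries()


@pytest.fixture(scope="session")
def daylight_bg(primaries):
    return sd.make_background(primaries)


@pytest.fixture(scope="session")
def reduced_s_bg(primaries):
    return sd.make_background(primaries, "reduced-S")


@pytest.fixture(scope="session")
def battery(primaries, daylight_bg):
    """The four cone stimuli plus rod stimulus, solved once per session."""
    c = 0.75
    specs = {
        "L_Only": sd.ContrastSpec.isolate("L", c, ["S"], ["rod", "mel"]),
        "S_Only": sd.ContrastSpec.isolate("S", c, ["L"], ["rod", "mel"]),
        "L+S": sd.ContrastSpec({"L": ("target", c), "S": ("target", c),
                                "rod": ("minimize", None),
                                "mel": ("minimize", None)}),
        "L-S": sd.ContrastSpec({"L": ("target", c), "S": ("target", -c),
                                "rod": ("minimize", None),
                                "mel": ("minimize", None)}),
        "Rod": sd.ContrastSpec({"rod": ("target", 0.45),
                                "L": ("silenced", 0.0),
                                "S": ("silenced", 0.0)}),
    }
    return {k: sd.solve_silent_substitution(primaries, daylight_bg, v)
            for k, v in specs.items()}


@pytest.fixture(scope="session")
def square_waves(battery, primaries, daylight_bg):
    return {k: sd.build_square_wave(battery[k], primaries, daylight_bg,
                                    n_cycles=1)
            for k in ("L_Only", "S_Only", "L+S", "L-S")}


def make_null_trials(rng, rate=5.0, duration=4.0, n_trials=30, unit=0):
    from chromlgn.synthdata import TrialSpikes
    out = []
    for tr in range(n_trials):
        n = rng.poisson(rate * duration)
        out.append(TrialSpikes(unit, tr, np.sort(rng.random(n) * duration),
                               duration))
    return out
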