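import pytest

import wheatgap as wg
from wheatgap.crop import Management, simulate_years


@pytest.fixture(scope="session")
def weather():
    """Memoized weather generator shared across the suite (compile once,
    generate once per (site, years, seed))."""
    cache = {}

    def get(site_id: str, years: int, seed: int):
        key = (site_id, years, seed)
        if key not in cache:
            cache[key] = wg.generate_weather(wg.get_site(site_id), years, seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def rr_weather(weather):
    return weather("RR", 11, 1)


@pytest.fixture(scope="session")
def claire_rr_potential(rr_weather):
    return simulate_years(wg.CLAIRE, rr_weather,
                          management=Management(mode="potential"))


def random_cultivar(rng) -> "wg.CultivarParams":
    draw = {t: float(rng.uniform(lo, hi))
            for t, (lo, hi) in wg.TRAIT_BOUNDS.items()}
    return wg.CultivarParams(**draw, name="random")
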