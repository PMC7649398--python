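import pytest

from nutrex import AnimalClass, CowRecord, DietEntry, FeedComposition
from nutrex.synthetic import make_fixture


@pytest.fixture
def simple_feed():
    """One feed with round-number composition for hand-checkable intakes."""
    return {
        "grass": FeedComposition(feed_name="grass", dm=200, cp=150, p=5,
                                 ash=80, ddm=600)
    }


@pytest.fixture
def simple_cow():
    """Lactating cow eating 10 kg fresh of the simple feed, no leftovers."""
    return CowRecord(
        cow_id="c1", animal_class=AnimalClass.LACTATING, bw=433.0,
        milk_yield=13000.0, milk_protein=34.0, milk_p=0.6,
        diet=[DietEntry(feed_name="grass", offered_fresh=10_000.0)],
        faecal_n=24.0,
    )


@pytest.fixture(scope="session")
def tiny_herd():
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def default_herd():
    return make_fixture("paper-default", seed=11)
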