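"""Shared fixtures; the expensive enumerations are session-scoped."""

import pytest

from mdskit import (
    KmerSpace,
    brute_force_mds,
    enumerate_all_components,
    enumerate_cycles,
    mykkeltveit_set,
)


@pytest.fixture(scope="session")
def b2k2():
    return KmerSpace(2, 2)


@pytest.fixture(scope="session")
def b2k3():
    return KmerSpace(2, 3)


@pytest.fixture(scope="session")
def b2k4():
    return KmerSpace(2, 4)


@pytest.fixture(scope="session")
def b2k5():
    return KmerSpace(2, 5)


@pytest.fixture(scope="session")
def b2k6():
    return KmerSpace(2, 6)


@pytest.fixture(scope="session")
def b2k7():
    return KmerSpace(2, 7)


@pytest.fixture(scope="session")
def k4_mdss(b2k4):
    return brute_force_mds(b2k4)


@pytest.fixture(scope="session")
def k5_mdss(b2k5):
    return brute_force_mds(b2k5)


@pytest.fixture(scope="session")
def k4_cycles(b2k4):
    return enumerate_cycles(b2k4)


@pytest.fixture(scope="session")
def k4_summary(b2k4):
    return enumerate_all_components(b2k4, mykkeltveit_set(b2k4))


@pytest.fixture(scope="session")
def k6_summary(b2k6):
    return enumerate_all_components(b2k6, mykkeltveit_set(b2k6))


@pytest.fixture(scope="session")
def k7_summary(b2k7):
    return enumerate_all_components(b2k7, mykkeltveit_set(b2k7))
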