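import numpy as np
import pytest

from ncstream import default_parameters
from ncstream.engine import Snapshot


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return default_parameters()


def make_snapshot(
    pos,
    leader=None,
    vel=None,
    fn_pos=None,
    fn_fiber=None,
    fn_phi=None,
    t=720.0,
):
    """Build a Snapshot from plain lists (test convenience)."""
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    n = pos.shape[0]
    if leader is None:
        leader = np.zeros(n, dtype=bool)
    if vel is None:
        vel = np.zeros_like(pos)
    if fn_pos is None:
        fn_pos = np.zeros((0, 2))
    fn_pos = np.atleast_2d(np.asarray(fn_pos, dtype=float)) if len(fn_pos) else np.zeros((0, 2))
    m = fn_pos.shape[0]
    if fn_fiber is None:
        fn_fiber = np.zeros(m, dtype=bool)
    if fn_phi is None:
        fn_phi = np.zeros(m)
    return Snapshot(
        t=t,
        pos=pos,
        vel=np.asarray(vel, dtype=float),
        leader=np.asarray(leader, dtype=bool),
        fn_pos=fn_pos,
        fn_fiber=np.asarray(fn_fiber, dtype=bool),
        fn_phi=np.asarray(fn_phi, dtype=float),
    )
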