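import numpy as np
import pytest

import metcomp as mc


@pytest.fixture
def quick_options():
    """Solver options sized for unit tests (the portfolio of structured
    starts does most of the work; a few random starts guard against bias)."""
    return mc.SolverOptions(n_starts=6, seed=123)


@pytest.fixture
def strong_inhibition_model():
    """Strong feedback inhibition, permeable intermediate, poorly permeable
    product: the canonical complementation setting."""
    return mc.default_consortium(inv_K_I=10.0, D_X=10.0, D_P=0.1)


@pytest.fixture
def weak_inhibition_model():
    return mc.default_consortium(inv_K_I=0.1, D_X=10.0, D_P=0.1)


def single_cell_steady_state(kinetics, enzymes, substrate):
    """Independent root-finding oracle for one isolated cell (m = 1).

    Solves V_S = V_X = V_P for (X, P) by Newton iteration from several
    starts; returns (X, P, V_P) or None if no root is found.
    """
    from scipy.optimize import fsolve

    from metcomp.kinetics import consumption_rate, synthesis_rate

    kin_S, kin_X, kin_P = kinetics
    E_S, E_X, E_P = enzymes

    def f(w):
        X, P = np.exp(np.clip(w, -40, 12))
        vs = synthesis_rate(kin_S, E_S, substrate, X, P)
        vx = synthesis_rate(kin_X, E_X, X, P)
        vp = consumption_rate(kin_P, E_P, P)
        return [vs - vx, vx - vp]

    for guess in [(1, 1), (0.1, 0.1), (5, 0.5), (0.01, 2)]:
        w, info, ier, _ = fsolve(f, np.log(guess), full_output=True)
        if ier == 1 and np.max(np.abs(info["fvec"])) < 1e-10:
            X, P = np.exp(np.clip(w, -40, 12))
            return X, P, consumption_rate(kin_P, E_P, P)
    return None


def single_cell_brute_force_optimum(kinetics, substrate, demand=1.0,
                                    rounds=6, npts=7):
    """Exhaustive refined grid search over log enzyme concentrations for
    one isolated cell: the independent optimization oracle."""
    lo, hi = np.full(3, -2.0), np.full(3, 2.0)
    best = None
    for _ in range(rounds):
        grids = [np.linspace(lo[i], hi[i], npts) for i in range(3)]
        for a in grids[0]:
            for b in grids[1]:
                for c in grids[2]:
                    E = 10.0 ** np.array([a, b, c])
                    st = single_cell_steady_state(kinetics, E, substrate)
                    if st is not None and st[2] >= demand * (1 - 1e-9):
                        tot = float(E.sum())
                        if best is None or tot < best[0]:
                            best = (tot, (a, b, c))
        center = np.array(best[1])
        width = (hi - lo) / npts * 1.6
        lo, hi = center - width, center + width
    return best[0]
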