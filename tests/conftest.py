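import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tdadft.fixtures import generate_fixture
from tdadft.functionals import FunctionalSpec, make_functional
from tdadft.response import ResponseEngine
from tdadft.scf import SCFOptions, build_environment, run_scf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _functional(name: str) -> FunctionalSpec:
    if name == "hf":
        # pure Hartree-Fock host: all exchange is Fock, no correlation
        return FunctionalSpec("hf", c_F=1.0, cam_alpha=1.0, correlation="none")
    return make_functional(name)


class SystemCache:
    """Converged SCF + response engines, shared across the whole session."""

    def __init__(self) -> None:
        self._cache: dict = {}

    def fixture(self, name: str, basis: str = "sto-3g"):
        key = ("fx", name, basis)
        if key not in self._cache:
            fx = generate_fixture(name, basis)
            self._cache[key] = (fx, fx.molecule, fx.ao_basis(), fx.aux_basis())
        return self._cache[key]

    def scf(self, name: str, functional: str = "lda", basis: str = "sto-3g",
            need_4c: bool | None = None, grid_level: str = "default"):
        key = ("scf", name, functional, basis, bool(need_4c), grid_level)
        if key not in self._cache:
            _, mol, aos, aux = self.fixture(name, basis)
            func = _functional(functional)
            env = build_environment(mol, aos, aux, func, grid_level, need_4c)
            res, env = run_scf(mol, aos, aux, func, SCFOptions(grid_level=grid_level),
                               environment=env)
            self._cache[key] = (res, env)
        return self._cache[key]

    def engine(self, name: str, functional: str = "lda", basis: str = "sto-3g",
               need_4c: bool | None = None) -> ResponseEngine:
        key = ("eng", name, functional, basis, bool(need_4c))
        if key not in self._cache:
            res, env = self.scf(name, functional, basis, need_4c)
            self._cache[key] = ResponseEngine(res, env)
        return self._cache[key]


@pytest.fixture(scope="session")
def systems() -> SystemCache:
    return SystemCache()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
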