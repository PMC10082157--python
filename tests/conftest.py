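import numpy as np
import pytest
from hypothesis import settings

from bitescreen.library_design import (
    ALL_ORIENTATIONS,
    AMINO_ACIDS,
    AnchorSet,
    DegenerateScheme,
    LibraryDefinition,
    ScFvRef,
    Target,
)
from bitescreen.screen_sim import default_linker_panel, synthetic_panel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

_FORBIDDEN = ("GGGGS", "EAAAK", "HHH")


def _domain(rng: np.random.Generator, length: int) -> str:
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    while True:
        seq = rng.choice(aas, size=length).tobytes().decode()
        if not any(m in seq for m in _FORBIDDEN):
            return seq


@pytest.fixture(scope="session")
def toy_defn() -> LibraryDefinition:
    """Small two-binder-per-arm panel with short domains and a 4-residue
    CDRH3 window; cheap enough for brute-force oracles."""
    rng = np.random.default_rng(42)
    cd19 = tuple(
        ScFvRef(name, Target.CD19, _domain(rng, 30), _domain(rng, 24),
                cdrh3_start=20, cdrh3_end=24)
        for name in ("tA", "tB")
    )
    cd3 = tuple(
        ScFvRef(name, Target.CD3, _domain(rng, 30), _domain(rng, 24))
        for name in ("tC", "tD")
    )
    return LibraryDefinition(
        cd19_refs=cd19,
        cd3_refs=cd3,
        linkers=default_linker_panel(),
        orientations=ALL_ORIENTATIONS,
        scheme=DegenerateScheme(),
        anchors=AnchorSet(),
    )


@pytest.fixture(scope="session")
def panel() -> LibraryDefinition:
    """Full-size synthetic reference panel (8 binders, 4 linkers)."""
    return synthetic_panel(0)
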