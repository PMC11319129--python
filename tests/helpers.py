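"""Shared constructors for hand-built observations."""
from rhizostoich import (
    DesignKey,
    EnzymeProfile,
    PlotObservation,
    RootChemistry,
    SoilChemistry,
)

BULK = dict(soc=20.0, tn=1.5, tp=0.55, nh4=8.0, no3=6.0, ap=4.0)
ENZ = dict(bg=30.0, nag=50.0, lap=33.0, acp=40.0)
ROOT = dict(tc=450.0, tn=12.0, tp=0.9)


def make_observation(rhizo_scale=None, enzymes=None, root=None,
                     key=("42", "N0", "B1")):
    """One plot; rhizo soil equals bulk unless per-variable scaled."""
    scale = rhizo_scale or {}
    rhizo = {k: v * scale.get(k, 1.0) for k, v in BULK.items()}
    age, nl, block = key
    return PlotObservation(
        key=DesignKey(int(age), nl, block, plot=f"{age}-{nl}-{block}"),
        rhizo_soil=SoilChemistry(**rhizo),
        bulk_soil=SoilChemistry(**BULK),
        rhizo_enzymes=EnzymeProfile(**(enzymes or ENZ)),
        root=RootChemistry(**(root or ROOT)),
    )
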