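"""Hypothesis strategies for valid LP scenarios."""

import hypothesis.strategies as st

from warburglp import UNLIMITED, ModelSpec

finite = dict(allow_nan=False, allow_infinity=False)


@st.composite
def model_specs(draw, allow_limited=True, allow_irreversible=True):
    alpha1 = draw(st.floats(0.0, 5.0, **finite))
    alpha2 = draw(st.floats(0.01, 5.0, **finite))
    alpha2_rev = draw(st.floats(0.0, 5.0, **finite))
    alpha3 = draw(
        st.floats(max(alpha1, alpha2, alpha2_rev) + 0.1, 100.0, **finite)
    )
    gamma = draw(st.floats(1.0, 1000.0, **finite))
    if allow_limited and draw(st.booleans()):
        v1 = draw(st.floats(0.0, 2.0 * gamma / (alpha1 + alpha2), **finite))
    else:
        v1 = UNLIMITED
    reversible = draw(st.booleans()) if allow_irreversible else True
    return ModelSpec.from_values(
        alpha1=alpha1,
        alpha2=alpha2,
        alpha2_rev=alpha2_rev,
        alpha3=alpha3,
        Gamma=gamma,
        V1=v1,
        fermentation_reversible=reversible,
    )


@st.composite
def mass_balanced_fluxes(draw):
    v2 = draw(st.floats(-1e3, 1e3, **finite))
    v3 = draw(st.floats(0.0, 1e3, **finite))
    return (v2, v3)
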