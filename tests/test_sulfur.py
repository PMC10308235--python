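"""Multiple-sulfur-isotope statistics, MSR forward model, and abundance
mass-balance mixing."""
import math

import pytest
from hypothesis import given, strategies as st

from quake_biogeo import (
    JUVENILE,
    MsrFractionation,
    SulfurRecord,
    cap_delta33,
    epsilon34,
    lambda33,
    mix_records,
    msr_forward,
    seawater_sulfate,
    sulfur_mixing_curve,
)
from quake_biogeo.sulfur import REFERENCE_EXPONENT

d34s = st.floats(min_value=-900.0, max_value=3000.0,
                 allow_nan=False, allow_infinity=False)


def reference_line_d33(d34: float, exponent: float = REFERENCE_EXPONENT) -> float:
    return ((1.0 + d34 / 1000.0) ** exponent - 1.0) * 1000.0


@given(d34=d34s)
def test_cap_delta33_zero_on_reference_line(d34):
    assert cap_delta33(reference_line_d33(d34), d34) == pytest.approx(0.0, abs=1e-9)


def test_cap_delta33_seawater_sulfate():
    # direct high-precision evaluation of the exact exponential form
    assert cap_delta33(10.963, 21.3) == pytest.approx(0.0496, abs=5e-4)
    assert round(cap_delta33(10.963, 21.3), 3) == 0.050
    assert cap_delta33(0.0, 0.0) == 0.0  # juvenile mantle sulfur


@pytest.mark.parametrize(
    "d34_sulfide, d34_sulfate, expected",
    [
        (21.3, 21.3, 0.0),
        (-47.95, 21.3, 67.8),   # largest fractionation vs seawater sulfate
        (-35.2, 21.3, 55.3),    # lowest-d34S CRS vs seawater sulfate
    ],
)
def test_epsilon34(d34_sulfide, d34_sulfate, expected):
    assert epsilon34(d34_sulfide, d34_sulfate) == pytest.approx(expected, abs=0.05)


@pytest.mark.parametrize("theta", [0.515, 0.514, 0.510])
def test_lambda33_recovers_construction_exponent(theta):
    sulfate = seawater_sulfate()
    d34_sf = -40.0
    ratio34 = (1000.0 + d34_sf) / (1000.0 + sulfate.delta34)
    d33_sf = (1000.0 + sulfate.delta33) * ratio34**theta - 1000.0
    assert lambda33(d33_sf, d34_sf, sulfate.delta33, sulfate.delta34) == (
        pytest.approx(theta, abs=1e-12)
    )


def test_lambda33_degenerate_when_d34_coincide():
    with pytest.raises(ZeroDivisionError):
        lambda33(5.0, 21.3, 10.963, 21.3)


def test_msr_forward_identity_and_round_trip():
    sulfate = seawater_sulfate()
    same = msr_forward(sulfate, MsrFractionation(0.0, 0.515))
    assert same.delta34 == pytest.approx(sulfate.delta34, abs=1e-12)
    assert same.delta33 == pytest.approx(sulfate.delta33, abs=1e-12)

    frac = MsrFractionation(67.8, 0.514)
    sulfide = msr_forward(sulfate, frac)
    assert sulfide.delta34 == pytest.approx(-47.95, abs=0.01)
    assert epsilon34(sulfide.delta34, sulfate.delta34) == pytest.approx(
        frac.eps34, abs=1e-9
    )
    assert lambda33(
        sulfide.delta33, sulfide.delta34, sulfate.delta33, sulfate.delta34
    ) == pytest.approx(frac.lambda33, abs=1e-9)


def test_msr_reference_exponent_preserves_cap_delta33_on_reference_line():
    # a sulfate pool sitting exactly on the 0.515 array stays on it under
    # lambda33 = 0.515 fractionation
    d34 = 21.3
    sulfate = SulfurRecord(reference_line_d33(d34), d34)
    sulfide = msr_forward(sulfate, MsrFractionation(60.0, 0.515))
    assert sulfide.cap_delta33 == pytest.approx(0.0, abs=1e-9)


def test_msr_reference_exponent_scales_offline_cap_delta33():
    # off the reference line, cap-delta33 transforms multiplicatively by
    # ((1+d34_sf/1000)/(1+d34_sa/1000))^0.515
    sulfate = seawater_sulfate()
    sulfide = msr_forward(sulfate, MsrFractionation(67.8, 0.515))
    factor = (
        (1000.0 + sulfide.delta34) / (1000.0 + sulfate.delta34)
    ) ** REFERENCE_EXPONENT
    assert sulfide.cap_delta33 == pytest.approx(
        sulfate.cap_delta33 * factor, abs=1e-9
    )


def test_msr_lambda_window_enforced():
    with pytest.raises(ValueError):
        MsrFractionation(60.0, 0.45)


def _abundance_oracle(end1, end2, f, r33_ref, r34_ref):
    """Brute-force molar mixing of 32S/33S/34S abundances."""
    moles = [0.0, 0.0, 0.0]
    for rec, amount in ((end1, 1.0 - f), (end2, f)):
        r33 = r33_ref * (1.0 + rec.delta33 / 1000.0)
        r34 = r34_ref * (1.0 + rec.delta34 / 1000.0)
        n32 = amount / (1.0 + r33 + r34)
        moles[0] += n32
        moles[1] += n32 * r33
        moles[2] += n32 * r34
    d33 = (moles[1] / moles[0] / r33_ref - 1.0) * 1000.0
    d34 = (moles[2] / moles[0] / r34_ref - 1.0) * 1000.0
    return d33, d34


def test_mixing_endpoints_and_oracle_agreement():
    sulfate = seawater_sulfate()
    biogenic = msr_forward(sulfate, MsrFractionation(30.0, 0.514))
    # endmember with cap-delta33 ~ +0.16 permil mixed toward juvenile sulfur
    curve = sulfur_mixing_curve(biogenic, JUVENILE, [0.0, 0.5, 1.0])
    assert curve[0][0] == pytest.approx(biogenic.delta34, abs=1e-12)
    assert curve[-1] == (pytest.approx(0.0, abs=1e-12), pytest.approx(0.0, abs=1e-12))

    r33, r34 = 0.0078776, 0.0441626
    d33, d34 = _abundance_oracle(biogenic, JUVENILE, 0.5, r33, r34)
    mid = mix_records(biogenic, JUVENILE, 0.5)
    assert mid.delta33 == pytest.approx(d33, abs=1e-10)
    assert mid.delta34 == pytest.approx(d34, abs=1e-10)
    assert curve[1][1] == pytest.approx(cap_delta33(d33, d34), abs=1e-10)


def test_mixing_insensitive_to_absolute_reference_scale():
    sulfate = seawater_sulfate()
    biogenic = msr_forward(sulfate, MsrFractionation(67.8, 0.514))
    base = mix_records(biogenic, JUVENILE, 0.5, reference_ratios=(0.0078776, 0.0441626))
    for scale in (0.5, 2.0):
        scaled = mix_records(
            biogenic, JUVENILE, 0.5,
            reference_ratios=(0.0078776 * scale, 0.0441626 * scale),
        )
        assert scaled.delta34 == pytest.approx(base.delta34, abs=0.05)
        assert scaled.cap_delta33 == pytest.approx(base.cap_delta33, abs=1e-3)


def test_mixing_associative_three_components():
    a = seawater_sulfate()
    b = msr_forward(a, MsrFractionation(55.3, 0.514))
    c = JUVENILE
    f, g = 0.3, 0.4
    nested = mix_records(mix_records(a, b, f), c, g)
    # closed-form three-component weights
    r33, r34 = 0.0078776, 0.0441626
    moles = [0.0, 0.0, 0.0]
    for rec, w in ((a, (1 - f) * (1 - g)), (b, f * (1 - g)), (c, g)):
        rr33 = r33 * (1.0 + rec.delta33 / 1000.0)
        rr34 = r34 * (1.0 + rec.delta34 / 1000.0)
        n32 = w / (1.0 + rr33 + rr34)
        moles[0] += n32
        moles[1] += n32 * rr33
        moles[2] += n32 * rr34
    d33 = (moles[1] / moles[0] / r33 - 1.0) * 1000.0
    d34 = (moles[2] / moles[0] / r34 - 1.0) * 1000.0
    assert nested.delta33 == pytest.approx(d33, abs=1e-6)
    assert nested.delta34 == pytest.approx(d34, abs=1e-6)


def test_mixing_curve_approaches_line_for_small_d34_contrast():
    sulfate = seawater_sulfate()

    def midpoint_deviation(end2):
        f = 0.5
        mid = mix_records(sulfate, end2, f)
        linear = (1 - f) * sulfate.cap_delta33 + f * end2.cap_delta33
        return abs(mid.cap_delta33 - linear)

    far = SulfurRecord(reference_line_d33(-40.0) + 0.16, -40.0)
    near = SulfurRecord(reference_line_d33(21.0) + 0.16, 21.0)
    assert midpoint_deviation(near) < midpoint_deviation(far)
    assert midpoint_deviation(near) < 1e-4


def test_outputs_continuous_under_tiny_perturbation():
    sulfate = seawater_sulfate()
    base = cap_delta33(sulfate.delta33, sulfate.delta34)
    bumped = cap_delta33(sulfate.delta33 + 1e-9, sulfate.delta34 + 1e-9)
    assert bumped == pytest.approx(base, abs=1e-6)
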