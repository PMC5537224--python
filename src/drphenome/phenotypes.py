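"""Derived physiological phenotypes.

Closed-form measures computed from raw instrument readouts in a mouse
phenotyping screen: indirect calorimetry (RER, heat production),
M-mode echocardiography (fractional shortening, Teichholz volumes,
ejection fraction, corrected LV mass, stroke volume, cardiac output),
surface electrocardiography (Bazett-corrected QT, HRV, rMSSD, pNN50)
and impedance hematology (HCT, MCH, MCHC, PCT).

Unit conventions, fixed at the interface:

========================  ==========================
quantity                  unit
========================  ==========================
VO2, VCO2                 ml gas / h
heat production           mW
echo linear dimensions    mm
LV volumes                ul
LV mass                   mg
ECG intervals             ms (RR in s for QTc)
MCV, MPV                  fl
RBC                       10^6 cells / ul
PLT                       10^3 cells / ul
HGB, MCHC                 g/dl
HCT                       fraction
========================  ==========================

All functions are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "respiratory_exchange_ratio",
    "heat_production",
    "fractional_shortening",
    "teichholz_volume",
    "ejection_fraction",
    "lv_mass_corrected",
    "stroke_and_output",
    "qtc_bazett",
    "hematology_derived",
    "hrv_metrics",
    "qt_dispersion",
    "percent_reduction",
    "derive_table",
]


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be > 0")


def respiratory_exchange_ratio(vco2, vo2):
    """RER = VCO2/VO2 (dimensionless; ~0.7 lipid, ~1.0 carbohydrate fuel)."""
    _check_positive(vo2=vo2)
    if np.any(np.asarray(vco2) < 0):
        raise ValueError("vco2 must be >= 0")
    return np.divide(vco2, vo2)


def heat_production(vo2, rer):
    """Heat production HP (mW) = (4.44 + 1.43 * RER) * VO2 (ml/h)."""
    _check_positive(vo2=vo2, rer=rer)
    return (4.44 + 1.43 * np.asarray(rer)) * vo2


def fractional_shortening(lvidd, lvids):
    """FS% = 100 * (LVIDd - LVIDs) / LVIDd."""
    _check_positive(lvidd=lvidd)
    return 100.0 * (np.asarray(lvidd) - lvids) / lvidd


def teichholz_volume(lvid):
    """Teichholz LV volume (ul) from one M-mode diameter: 7.0/(2.4+LVID) * LVID^3."""
    _check_positive(lvid=lvid)
    lvid = np.asarray(lvid, dtype=float)
    return 7.0 / (2.4 + lvid) * lvid**3


def ejection_fraction(lvidd, lvids):
    """EF% = 100 * (LVvolD - LVvolS) / LVvolD with Teichholz volumes."""
    _check_positive(lvidd=lvidd)
    if np.any(np.asarray(lvids) < 0):
        raise ValueError("lvids must be >= 0")
    vd = teichholz_volume(lvidd)
    lvids = np.asarray(lvids, dtype=float)
    vs = np.where(lvids > 0, 7.0 / (2.4 + lvids) * lvids**3, 0.0)
    return 100.0 * (vd - vs) / vd


def lv_mass_corrected(lvidd, lvpwd, ivsd):
    """Corrected LV mass (mg) = 0.8 * 1.053 * ((LVIDd+LVPWd+IVSd)^3 - LVIDd^3).

    Wall thicknesses of zero are admitted (zero mass limit); the internal
    diameter must be positive.
    """
    _check_positive(lvidd=lvidd)
    if np.any(np.asarray(lvpwd) < 0) or np.any(np.asarray(ivsd) < 0):
        raise ValueError("wall thicknesses must be >= 0")
    lvidd = np.asarray(lvidd, dtype=float)
    return 0.8 * 1.053 * ((lvidd + lvpwd + ivsd) ** 3 - lvidd**3)


def stroke_and_output(lvidd, lvids, heart_rate):
    """Stroke volume (ul) and cardiac output (ul/min).

    SV = Teichholz(LVIDd) - Teichholz(LVIDs); CO = SV * heart rate.
    """
    _check_positive(lvidd=lvidd, heart_rate=heart_rate)
    sv = teichholz_volume(lvidd) - np.where(
        np.asarray(lvids) > 0, teichholz_volume(np.maximum(lvids, 1e-300)), 0.0
    )
    return sv, sv * heart_rate


def qtc_bazett(qt_ms, rr_s):
    """Bazett rate-corrected QT: QT (ms) / sqrt(RR (s)).

    RR enters in seconds (the classic Bazett convention). Some mouse ECG
    literature instead normalizes RR to 100 ms; callers using that
    convention must rescale before calling.
    """
    _check_positive(rr_s=rr_s)
    return np.asarray(qt_ms) / np.sqrt(rr_s)


def qt_dispersion(qtc_values):
    """Inter-lead (or inter-beat) QTc dispersion, as range max - min.

    The dispersion definition is the spread of corrected QT across the
    provided measurements; range is used here (an assumption documented
    in the methods note — an SD-based definition is equally defensible).
    """
    qtc_values = np.asarray(qtc_values, dtype=float)
    if qtc_values.size < 1:
        raise ValueError("need at least one QTc value")
    return float(qtc_values.max() - qtc_values.min())


def hematology_derived(mcv_fl, rbc_mill_per_ul, hgb_g_dl, mpv_fl, plt_k_per_ul):
    """Derived red-cell and platelet indices.

    HCT  = MCV * RBC          (fraction; fl * 10^6/ul -> /1000)
    MCH  = HGB / RBC          (pg/cell; g/dl / 10^6/ul -> *10)
    MCHC = HGB / HCT          (g/dl)
    PCT  = MPV * PLT          (percent; fl * 10^3/ul -> /10^4)

    Returns ``(hct, mch_pg, mchc_g_dl, pct_pct)``.
    """
    _check_positive(
        mcv_fl=mcv_fl,
        rbc_mill_per_ul=rbc_mill_per_ul,
        hgb_g_dl=hgb_g_dl,
        mpv_fl=mpv_fl,
        plt_k_per_ul=plt_k_per_ul,
    )
    hct = np.asarray(mcv_fl) * rbc_mill_per_ul / 1000.0
    mch = 10.0 * np.asarray(hgb_g_dl) / rbc_mill_per_ul
    mchc = np.asarray(hgb_g_dl) / hct
    pct = np.asarray(mpv_fl) * plt_k_per_ul / 1.0e4
    return hct, mch, mchc, pct


def hrv_metrics(rr_ms):
    """Heart-rate variability from a series of RR intervals (ms).

    HRV    mean absolute successive difference of RR intervals
    rMSSD  root mean square of successive differences
    pNN50  percentage of successive differences exceeding 50 ms

    Signed successive differences average to roughly zero in any
    stationary series, so HRV uses the absolute differences.

    Returns ``(hrv_ms, rmssd_ms, pnn50_pct)``.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.ndim != 1 or rr.size < 2:
        raise ValueError("need at least two RR intervals")
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be > 0")
    d = np.diff(rr)
    hrv = float(np.mean(np.abs(d)))
    rmssd = float(np.sqrt(np.mean(d**2)))
    pnn50 = float(100.0 * np.mean(np.abs(d) > 50.0))
    return hrv, rmssd, pnn50


def percent_reduction(control, treated):
    """Percent reduction of a quantity relative to control: 100*(c-t)/c."""
    _check_positive(control=control)
    return 100.0 * (np.asarray(control) - treated) / control


# ---------------------------------------------------------------------------
# Vectorized table interface

#: raw column -> derived column mapping applied by :func:`derive_table`
DERIVED_COLUMNS = (
    "rer",
    "hp_mw",
    "fs_pct",
    "ef_pct",
    "lv_mass_mg",
    "sv_ul",
    "co_ul_min",
    "qtc",
    "hct",
    "mch_pg",
    "mchc_gdl",
    "pct_pct",
)


def derive_table(df):
    """Append derived-phenotype columns to a raw-measure table.

    Looks for the raw columns each formula needs (``vo2_ml_h``,
    ``vco2_ml_h``, ``lvidd_mm``, ``lvids_mm``, ``ivsd_mm``, ``lvpwd_mm``,
    ``heart_rate_bpm``, ``qt_ms``, ``rr_s``, ``mcv_fl``, ``rbc_mill_ul``,
    ``hgb_g_dl``, ``mpv_fl``, ``plt_k_ul``) and appends whichever derived
    columns are computable; missing raw columns are skipped silently.
    Returns a new DataFrame.
    """
    out = df.copy()
    cols = set(df.columns)
    if {"vco2_ml_h", "vo2_ml_h"} <= cols:
        out["rer"] = respiratory_exchange_ratio(df["vco2_ml_h"], df["vo2_ml_h"])
        out["hp_mw"] = heat_production(df["vo2_ml_h"], out["rer"])
    if {"lvidd_mm", "lvids_mm"} <= cols:
        out["fs_pct"] = fractional_shortening(df["lvidd_mm"], df["lvids_mm"])
        out["ef_pct"] = ejection_fraction(df["lvidd_mm"], df["lvids_mm"])
        if "heart_rate_bpm" in cols:
            sv, co = stroke_and_output(
                df["lvidd_mm"], df["lvids_mm"], df["heart_rate_bpm"]
            )
            out["sv_ul"], out["co_ul_min"] = sv, co
    if {"lvidd_mm", "lvpwd_mm", "ivsd_mm"} <= cols:
        out["lv_mass_mg"] = lv_mass_corrected(
            df["lvidd_mm"], df["lvpwd_mm"], df["ivsd_mm"]
        )
    if {"qt_ms", "rr_s"} <= cols:
        out["qtc"] = qtc_bazett(df["qt_ms"], df["rr_s"])
    if {"mcv_fl", "rbc_mill_ul", "hgb_g_dl", "mpv_fl", "plt_k_ul"} <= cols:
        hct, mch, mchc, pct = hematology_derived(
            df["mcv_fl"], df["rbc_mill_ul"], df["hgb_g_dl"], df["mpv_fl"], df["plt_k_ul"]
        )
        out["hct"], out["mch_pg"], out["mchc_gdl"], out["pct_pct"] = hct, mch, mchc, pct
    return out
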