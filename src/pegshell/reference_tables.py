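"""Published per-system summary statistics for the seven PEG-coated
nanoparticle systems (100 ns all-atom MD, last-10 ns analysis window).

These transcribed values are comparison-test inputs for the reporting
machinery — reference data to difference against, never outputs of this
package's analyses.  Energies in kcal·mol⁻¹, lengths in Å; ``*_std`` are
the published standard deviations.  ``hbonds_peg_water`` is the mean
PEG/water hydrogen-bond count where published.
"""

from __future__ import annotations

#: Mean structural and energetic quantities per system.
SYSTEM_TABLES: dict[str, dict[str, float]] = {
    "ND^2-25PEG_500-OH": {
        "n_chains": 25,
        "Rg": 6.4, "Rg_std": 0.1,
        "h": 16.0, "h_std": 2.0,
        "d": 22.0, "d_std": 3.0,
        "thk": 12.46, "thk_std": 0.03,
        "E_np_peg": -35.0, "E_peg_peg": -1459.0,
        "E_np_water": -37.0, "E_peg_water": -3280.0,
        "hbonds_peg_water": 78.0,
    },
    "ND^2-50PEG_500-OH": {
        "n_chains": 50,
        "Rg": 7.0, "Rg_std": 0.1,
        "h": 18.0, "h_std": 2.0,
        "d": 27.0, "d_std": 2.0,
        "thk": 16.48, "thk_std": 0.03,
        "E_np_peg": 218.0, "E_peg_peg": -3090.0,
        "E_np_water": -3.0, "E_peg_water": -6109.0,
        "hbonds_peg_water": 153.0,
    },
    "ND^2-100PEG_500-OH": {
        "n_chains": 100,
        "Rg": 7.6, "Rg_std": 0.1,
        "h": 21.0, "h_std": 2.0,
        "d": 31.0, "d_std": 2.0,
        "thk": 20.18, "thk_std": 0.03,
        "E_np_peg": 449.0, "E_peg_peg": -6042.0,
        "E_np_water": -5.0, "E_peg_water": -10782.0,
        "hbonds_peg_water": 262.0,
    },
    "ND^2-50PEG_500-CH3": {
        "n_chains": 50,
        "Rg": 7.1, "Rg_std": 0.1,
        "h": 19.0, "h_std": 2.0,
        "d": 28.0, "d_std": 3.0,
        "thk": 16.88, "thk_std": 0.03,
        "E_np_peg": 215.0, "E_peg_peg": -1969.0,
        "E_np_water": 0.0, "E_peg_water": -4609.0,
        "hbonds_peg_water": 151.0,
    },
    "TiO2^2-50PEG_500-CH3": {
        "n_chains": 50,
        "Rg": 6.7, "Rg_std": 0.1,
        "h": 17.0, "h_std": 0.5,
        "d": 27.0, "d_std": 2.0,
        "thk": 15.17, "thk_std": 0.03,
        "E_np_peg": -485.0, "E_peg_peg": -1262.0,
        "E_np_water": -420.0, "E_peg_water": -5205.0,
    },
    "ND^5-360PEG_500-OH": {
        "n_chains": 360,
        "Rg": 7.99, "Rg_std": 0.02,
        "h": 22.0, "h_std": 2.0,
        "d": 46.0, "d_std": 2.0,
        "thk": 22.03, "thk_std": 0.03,
        "E_np_peg": 3363.0, "E_peg_peg": -24247.0,
        "E_np_water": -26.0, "E_peg_water": -33022.0,
    },
    "ND^5-360PEG_1000-OH": {
        "n_chains": 360,
        "Rg": 12.40, "Rg_std": 0.04,
        "h": 36.0, "h_std": 3.0,
        "d": 60.0, "d_std": 3.0,
        "thk": 34.84, "thk_std": 0.03,
        "E_np_peg": 3346.0, "E_peg_peg": -28589.0,
        "E_np_water": 5.0, "E_peg_water": -74886.0,
    },
}

#: Published comparative percent changes (magnitude, rounded to integer %)
#: among the systems above.  Each row: quantity, reference system, other
#: system, options, expected percent.  ``magnitude`` differences energies by
#: absolute value; ``per_chain`` normalizes by the chain count first.
COMPARISON_PLAN: list[dict] = [
    # grafting density: 100 vs 50 chains
    {"quantity": "Rg", "reference": "ND^2-50PEG_500-OH", "other": "ND^2-100PEG_500-OH", "expected": 9},
    {"quantity": "h", "reference": "ND^2-50PEG_500-OH", "other": "ND^2-100PEG_500-OH", "expected": 17},
    {"quantity": "d", "reference": "ND^2-50PEG_500-OH", "other": "ND^2-100PEG_500-OH", "expected": 15},
    {"quantity": "thk", "reference": "ND^2-50PEG_500-OH", "other": "ND^2-100PEG_500-OH", "expected": 22},
    # grafting density: 100 vs 25 chains
    {"quantity": "Rg", "reference": "ND^2-25PEG_500-OH", "other": "ND^2-100PEG_500-OH", "expected": 19},
    {"quantity": "h", "reference": "ND^2-25PEG_500-OH", "other": "ND^2-100PEG_500-OH", "expected": 31},
    {"quantity": "d", "reference": "ND^2-25PEG_500-OH", "other": "ND^2-100PEG_500-OH", "expected": 41},
    {"quantity": "thk", "reference": "ND^2-25PEG_500-OH", "other": "ND^2-100PEG_500-OH", "expected": 62},
    # core dimension: 5 nm/360 chains vs 2 nm/100 chains
    {"quantity": "Rg", "reference": "ND^2-100PEG_500-OH", "other": "ND^5-360PEG_500-OH", "expected": 5},
    {"quantity": "h", "reference": "ND^2-100PEG_500-OH", "other": "ND^5-360PEG_500-OH", "expected": 5},
    {"quantity": "thk", "reference": "ND^2-100PEG_500-OH", "other": "ND^5-360PEG_500-OH", "expected": 9},
    {"quantity": "E_peg_water", "reference": "ND^2-100PEG_500-OH", "other": "ND^5-360PEG_500-OH",
     "magnitude": True, "per_chain": True, "expected": 15},
    # polymer length: PEG1000 vs PEG500 on the 5 nm core
    {"quantity": "Rg", "reference": "ND^5-360PEG_500-OH", "other": "ND^5-360PEG_1000-OH", "expected": 55},
    {"quantity": "h", "reference": "ND^5-360PEG_500-OH", "other": "ND^5-360PEG_1000-OH", "expected": 64},
    {"quantity": "d", "reference": "ND^5-360PEG_500-OH", "other": "ND^5-360PEG_1000-OH", "expected": 30},
    {"quantity": "thk", "reference": "ND^5-360PEG_500-OH", "other": "ND^5-360PEG_1000-OH", "expected": 58},
    {"quantity": "E_peg_peg", "reference": "ND^5-360PEG_500-OH", "other": "ND^5-360PEG_1000-OH",
     "magnitude": True, "expected": 18},
    {"quantity": "E_peg_water", "reference": "ND^5-360PEG_500-OH", "other": "ND^5-360PEG_1000-OH",
     "magnitude": True, "expected": 127},
    # core material: TiO2 vs ND (reductions)
    {"quantity": "Rg", "reference": "ND^2-50PEG_500-CH3", "other": "TiO2^2-50PEG_500-CH3", "expected": 6},
    {"quantity": "h", "reference": "ND^2-50PEG_500-CH3", "other": "TiO2^2-50PEG_500-CH3", "expected": 11},
    {"quantity": "d", "reference": "ND^2-50PEG_500-CH3", "other": "TiO2^2-50PEG_500-CH3", "expected": 4},
    {"quantity": "thk", "reference": "ND^2-50PEG_500-CH3", "other": "TiO2^2-50PEG_500-CH3", "expected": 10},
]
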