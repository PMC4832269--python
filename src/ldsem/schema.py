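"""Variable naming for the two-wave brain/cognition cohort.

Twelve cognitive tests load on three latent domains (fluid intelligence,
memory, processing speed); two pencil-and-paper speed tests cross-load on
fluid intelligence.  Four brain volumes (total brain, grey matter,
normal-appearing white matter, white-matter hyperintensities) are measured
once per wave.  Waves are suffixed ``_w1`` (mean age 73) and ``_w2``
(mean age 76).
"""

from __future__ import annotations

FACTORS = ("fluid", "memory", "speed")

#: indicator tests per latent domain, in canonical order (first test anchors
#: the factor's scale via a unit loading)
FACTOR_TESTS: dict[str, tuple[str, ...]] = {
    "fluid": (
        "matrix_reasoning",
        "block_design",
        "digit_span_backward",
        "letter_number_sequencing",
    ),
    "memory": (
        "logical_memory",
        "verbal_paired_associates",
        "spatial_span",
    ),
    "speed": (
        "digit_symbol",
        "symbol_search",
        "simple_rt",
        "choice_rt",
        "inspection_time",
    ),
}

#: (test, extra factor) cross-loadings
CROSS_LOADINGS: tuple[tuple[str, str], ...] = (
    ("digit_symbol", "fluid"),
    ("symbol_search", "fluid"),
)

TESTS: tuple[str, ...] = tuple(t for f in FACTORS for t in FACTOR_TESTS[f])

VOLUMES = ("tbv", "gm", "nawm", "wmh")
MODEL_A_VOLUMES = ("tbv",)
MODEL_B_VOLUMES = ("gm", "nawm", "wmh")

WAVES = ("w1", "w2")

SEX_COL = "sex"  # 0 = female, 1 = male
AGE_COLS = {
    ("cog", "w1"): "age_days_cog_w1",
    ("cog", "w2"): "age_days_cog_w2",
    ("mri", "w1"): "age_days_mri_w1",
    ("mri", "w2"): "age_days_mri_w2",
}
MMSE_COLS = {"w1": "mmse_w1", "w2": "mmse_w2"}
DEMENTIA_COL = "dementia_diagnosis"
ID_COL = "subject_id"


def col(var: str, wave: str) -> str:
    """Column name of a longitudinal variable at a wave."""
    return f"{var}_{wave}"


def latent(factor: str, wave: str) -> str:
    return f"{factor}_{wave}"


def change(var: str) -> str:
    """Name of the latent change variable of a level variable."""
    return f"d_{var}"


def age_col_for(var: str, wave: str) -> str:
    """Age covariate matching a variable: scan age for volumes, testing age
    for cognitive tests."""
    kind = "mri" if var in VOLUMES else "cog"
    return AGE_COLS[(kind, wave)]


def model_variables(model: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(observed columns, volume names) entering Model A or B."""
    model = model.upper()
    if model == "A":
        vols = MODEL_A_VOLUMES
    elif model == "B":
        vols = MODEL_B_VOLUMES
    else:
        raise ValueError(f"unknown model {model!r}")
    cols = [col(t, w) for w in WAVES for t in TESTS]
    cols += [col(v, w) for w in WAVES for v in vols]
    return tuple(cols), vols


def cohort_columns() -> list[str]:
    """Full column inventory of a simulated cohort table."""
    cols = [ID_COL, SEX_COL] + list(AGE_COLS.values())
    cols += [col(t, w) for w in WAVES for t in TESTS]
    cols += [col(v, w) for w in WAVES for v in VOLUMES]
    cols += [MMSE_COLS["w1"], MMSE_COLS["w2"], DEMENTIA_COL]
    return cols
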