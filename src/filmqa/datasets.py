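"""Bundled benchmark records from the clinical commissioning study of the
tray-film transmission QA.

Two record sets ship with the package:

* ``simple_field_records`` — the three square fields (5, 10 and 15 cm),
  an irregular field, and a five-field merged conformal delivery, each
  with its gamma pass rate, the film and TPS normalization-point doses
  (cGy), and the point-dose deviation as printed in the commissioning
  report (one decimal).  Two of the printed deviations are not exactly
  the rounded recomputation (the report evidently carried unrounded
  doses); ``deviation_rounds_exactly`` flags this.

* ``imrt_qa_records`` — the 25 controlled IMRT irradiations: five plans,
  each delivered five ways (two faithful 0° deliveries a week apart, one
  at the real gantry angles, one with reduced monitor units, one with a
  field removed).  Each record carries the TPS and film doses at the
  normalization point, the printed percent difference, the gamma pass
  rate, the printed QA result, and the outcome the delivery was
  engineered to produce.  The one discordant row (plan 5 at real gantry
  angles, printed Fail against an expected Pass) is attributed to a
  linac-output fluctuation and is what makes the study's headline
  concordance 24/25.

These numbers are measurement inputs for validating the verdict logic;
nothing in the package derives from them at run time.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["simple_field_records", "imrt_qa_records"]

_SIMPLE_FIELDS = [
    # configuration, gamma %, film cGy, TPS cGy, printed deviation %
    ("square 5 cm", 100.0, 150.3, 156.7, -4.1, True),
    ("square 10 cm", 99.9, 168.0, 168.9, -0.5, True),
    ("square 15 cm", 99.4, 178.2, 175.3, 1.6, False),
    ("irregular field", 99.9, 155.9, 163.0, -4.3, False),
    ("5 merged conformal fields", 99.9, 250.3, 249.6, 0.3, True),
]

# group, plan, TPS dose, film dose, printed %diff, gamma %, printed result,
# engineered outcome
_IMRT_QA = [
    ("0deg-1", 1, 245.6, 247.5, 0.8, 99.9, "Pass", "Pass"),
    ("0deg-1", 2, 185.7, 176.9, -4.7, 99.0, "Pass", "Pass"),
    ("0deg-1", 3, 253.0, 253.0, 0.0, 98.4, "Pass", "Pass"),
    ("0deg-1", 4, 230.2, 230.0, -0.1, 98.9, "Pass", "Pass"),
    ("0deg-1", 5, 207.5, 198.7, -4.2, 96.8, "Pass", "Pass"),
    ("0deg-2", 1, 245.3, 242.2, -1.3, 98.3, "Pass", "Pass"),
    ("0deg-2", 2, 185.7, 182.0, -2.0, 99.7, "Pass", "Pass"),
    ("0deg-2", 3, 255.9, 248.5, -2.9, 97.7, "Pass", "Pass"),
    ("0deg-2", 4, 230.2, 232.8, 1.1, 100.0, "Pass", "Pass"),
    ("0deg-2", 5, 197.9, 191.5, -3.2, 96.6, "Pass", "Pass"),
    ("real-gantry", 1, 245.9, 250.7, 2.0, 97.9, "Pass", "Pass"),
    ("real-gantry", 2, 173.5, 166.7, -3.9, 96.7, "Pass", "Pass"),
    ("real-gantry", 3, 252.8, 252.9, 0.0, 98.6, "Pass", "Pass"),
    ("real-gantry", 4, 230.2, 230.1, 0.0, 99.4, "Pass", "Pass"),
    ("real-gantry", 5, 207.5, 195.9, -5.6, 95.5, "Fail", "Pass"),
    ("lower-mu", 1, 245.8, 217.8, -11.4, 96.9, "Fail", "Fail"),
    ("lower-mu", 2, 173.5, 137.5, -20.7, 99.7, "Fail", "Fail"),
    ("lower-mu", 3, 252.6, 159.6, -36.8, 98.2, "Fail", "Fail"),
    ("lower-mu", 4, 230.2, 197.1, -14.4, 97.1, "Fail", "Fail"),
    ("lower-mu", 5, 208.7, 165.8, -20.6, 99.8, "Fail", "Fail"),
    ("field-removed", 1, 245.7, 220.1, -10.4, 92.9, "Fail", "Fail"),
    ("field-removed", 2, 185.7, 148.9, -19.8, 99.5, "Fail", "Fail"),
    ("field-removed", 3, 252.8, 226.4, -10.4, 47.3, "Fail", "Fail"),
    ("field-removed", 4, 230.2, 219.6, -4.6, 51.0, "Fail", "Fail"),
    ("field-removed", 5, 208.5, 159.1, -23.7, 70.2, "Fail", "Fail"),
]


def simple_field_records() -> pd.DataFrame:
    """The five simple-configuration QA records (square, irregular and
    merged-conformal fields)."""
    return pd.DataFrame(
        _SIMPLE_FIELDS,
        columns=[
            "configuration", "gamma_pass_pct", "dose_film_cGy", "dose_tps_cGy",
            "printed_deviation_pct", "deviation_rounds_exactly",
        ],
    )


def imrt_qa_records() -> pd.DataFrame:
    """The 25 controlled IMRT transmission-QA records (5 plans × 5
    delivery variants)."""
    return pd.DataFrame(
        _IMRT_QA,
        columns=[
            "group", "plan", "dose_tps_cGy", "dose_film_cGy",
            "printed_diff_pct", "gamma_pass_pct", "printed_result",
            "engineered_outcome",
        ],
    )
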