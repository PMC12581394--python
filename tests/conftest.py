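import pandas as pd
import pytest

from cdxval.calls import PairedCallTable


def make_table(rows):
    """Build a PairedCallTable from (ccd1, ccd2, fcd[, stratum]) tuples."""
    records = []
    for i, row in enumerate(rows):
        stratum = row[3] if len(row) > 3 else "unenriched"
        records.append(
            {
                "sample_id": f"S{i:04d}",
                "ccd1": row[0],
                "ccd2": row[1],
                "fcd": row[2],
                "stratum": stratum,
            }
        )
    return PairedCallTable(pd.DataFrame.from_records(records))


def table_from_counts(num: int, den: int):
    """Reference-positive table: `den` CCD1-positive rows, `num` FCD-positive."""
    rows = [("positive", "positive", "positive")] * num
    rows += [("positive", "positive", "negative")] * (den - num)
    return make_table(rows)


@pytest.fixture
def seven_row_table():
    """Hand fixture: 5 CCD1-positive rows of which 2 FCD-discordant -> PPA 3/5."""
    return make_table(
        [
            ("positive", "positive", "positive"),
            ("positive", "positive", "positive"),
            ("positive", "negative", "positive"),
            ("positive", "positive", "negative"),
            ("positive", "negative", "negative"),
            ("negative", "negative", "negative"),
            ("negative", "positive", "positive"),
        ]
    )
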