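import textwrap

import pandas as pd
import pytest
from hypothesis import settings

from pvsignal import srs_store, meddra

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


def write_csv(path, text):
    path.write_text(textwrap.dedent(text).lstrip())
    return path


@pytest.fixture
def small_tables(tmp_path):
    """Three-report fixture exercising roles, routes, aliases, partial dates."""
    demo = write_csv(tmp_path / "DEMO.csv", """
        case_id,version,sex,age_band,weight_band
        C1,1,male,20-59,40-69
        C2,1,female,>=60,unspecified
        C3,1,male,<20,<40
    """)
    drug = write_csv(tmp_path / "DRUG.csv", """
        case_id,version,drug_name,role,route,start_date,end_date
        C1,1,Cubicin,suspected,intravenous,2020-01-01,2020-01-10
        C1,1,linezolid,concomitant,oral,2020-01-02,
        C2,1,vancomycin,suspected,oral,2020-02-01,2020-02-14
        C3,1,daptomycin,concomitant,intravenous,2020-03-01,2020-03-08
    """)
    reac = write_csv(tmp_path / "REAC.csv", """
        case_id,version,pt_code,onset_date
        C1,1,pt_renal,2020-01-05
        C2,1,pt_rash,2021-04
        C3,1,pt_renal,2020-03-03
    """)
    hist = write_csv(tmp_path / "HIST.csv", """
        case_id,version,term
        C1,1,diabetes
    """)
    return {"demo": demo, "drug": drug, "reac": reac, "hist": hist}


@pytest.fixture
def small_report_set(small_tables):
    return srs_store.load_tables(small_tables["demo"], small_tables["drug"],
                                 small_tables["reac"], small_tables["hist"],
                                 alias_map={"Cubicin": "daptomycin"})


@pytest.fixture
def mini_dictionary(tmp_path):
    """Fictional PT->SMQ dictionary: many-to-many with both scopes."""
    path = write_csv(tmp_path / "dict.csv", """
        pt_code,smq_id,scope,smq_name
        pt_renal,smq_arf,narrow,Acute renal failure
        pt_renal,smq_kidney,broad,Kidney disorders
        pt_creatinine,smq_arf,narrow,Acute renal failure
        pt_rash,smq_skin,narrow,Skin reactions
        pt_itch,smq_skin,broad,Skin reactions
    """)
    return meddra.load_dictionary(path)


def make_report_set(drug_rows, reac_rows, n_extra_reports=0):
    """ReportSet from terse row tuples, plus optional empty filler reports.

    drug_rows: (case, drug, role, route, start, end); reac_rows:
    (case, pt, onset). Every referenced case plus filler cases get a DEMO
    row.
    """
    cases = sorted({r[0] for r in drug_rows} | {r[0] for r in reac_rows}
                   | {f"F{i:04d}" for i in range(n_extra_reports)})
    demo = pd.DataFrame({"case_id": cases, "version": 1, "sex": "male",
                         "age_band": "20-59", "weight_band": "40-69"})
    drug = pd.DataFrame(drug_rows, columns=["case_id", "drug_name", "role",
                                            "route", "start_date", "end_date"])
    drug.insert(1, "version", 1)
    reac = pd.DataFrame(reac_rows, columns=["case_id", "pt_code", "onset_date"])
    reac.insert(1, "version", 1)
    hist = pd.DataFrame(columns=["case_id", "version", "term"])
    return srs_store.ReportSet.from_frames(demo, drug, reac, hist)
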