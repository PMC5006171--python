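import textwrap

import pytest

from gwmethane.samples import read_samples


FIXTURE_CSV = textwrap.dedent(
    """\
    sample_id,aquifer_group,screen_depth_m,temperature_c,ph,do_mgl,na_mgl,ca_mgl,mg_mgl,hco3_mgl,cl_mgl,br_mgl,so4_mgl,no3_mgl,hs_mgl,fe_mgl,ch4_ugl,doc_mgl,d13c_ch4_permil,d2h_ch4_permil,d13c_dic_permil,d2h_h2o_permil,d18o_h2o_permil,d37cl_permil
    W01,GAS_RESERVOIR,320.0,30.5,8.2,0.1,1500.0,10.0,5.0,900.0,2500.0,6.5,<1,<0.01,<0.1,<0.05,12000.0,0.5,-53.5,-204.0,16.0,-38.6,-6.1,-1.2
    W02,SHALLOW_COAL_MEASURES,120.0,24.0,7.8,0.2,600.0,40.0,30.0,700.0,900.0,2.2,45.0,0.02,<0.1,0.3,4000.0,1.1,-74.5,-193.5,-9.7,-32.2,-4.9,0.1
    W03,ALLUVIUM,45.0,21.0,7.2,0.6,300.0,80.0,60.0,450.0,400.0,1.1,144.0,0.3,<0.1,,<10,2.0,,,-11.0,-30.0,-5.0,
    """
)


@pytest.fixture
def fixture_csv(tmp_path):
    path = tmp_path / "samples.csv"
    path.write_text(FIXTURE_CSV)
    return path


@pytest.fixture
def fixture_samples(fixture_csv):
    return read_samples(fixture_csv)
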