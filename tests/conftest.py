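import pytest

from gcmkit.fixtures import make_four_genome_suite, make_man_suite

MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:map99001" org="map" number="99001">
  <entry id="1" name="cpd:C00001" type="compound"><graphics name="A"/></entry>
  <entry id="2" name="cpd:C00002" type="compound"><graphics name="B"/></entry>
  <entry id="3" name="cpd:C00003" type="compound"><graphics name="C"/></entry>
  <reaction id="10" name="rn:R00001" type="irreversible">
    <substrate id="1"/><product id="2"/>
  </reaction>
  <reaction id="11" name="rn:R00002" type="irreversible">
    <substrate id="2"/><product id="3"/>
  </reaction>
</pathway>
"""

REVERSIBLE_KGML = """<?xml version="1.0"?>
<pathway name="path:map99002" org="map" number="99002">
  <entry id="1" name="cpd:C00001" type="compound"><graphics name="A"/></entry>
  <entry id="2" name="cpd:C00002" type="compound"><graphics name="B"/></entry>
  <reaction id="9" name="rn:R00009" type="reversible">
    <substrate id="1"/><product id="2"/>
  </reaction>
</pathway>
"""

TOY_PTT = """Toy chromosome, complete genome - 1..3000
3 proteins
Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct
1..900\t+\t299\t1001\tgenA\tT0001\t-\t-\tenzyme A
1001..1900\t-\t299\t1002\tgenB\tT0002\t-\t-\tenzyme B
2001..2900\t+\t299\t1003\tgenC\tT0003\t-\t-\tenzyme C
"""


@pytest.fixture(scope="session")
def four_genome_suite():
    return make_four_genome_suite()


@pytest.fixture(scope="session")
def man_suite():
    return make_man_suite()


@pytest.fixture()
def minimal_kgml():
    return MINIMAL_KGML


@pytest.fixture()
def reversible_kgml():
    return REVERSIBLE_KGML


@pytest.fixture()
def toy_ptt():
    return TOY_PTT
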