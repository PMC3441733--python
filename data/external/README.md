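# External catalog files

Place miRBase release-16 `mature.fa` and `miFam.dat` here to run the
real-data seed census (`analysis/01_seed_census.py --mature
data/external/mature.fa --families data/external/miFam.dat`) and the
corresponding acceptance-level test. On the human (`hsa`) entries of that
release, the 2–7 seed census yields 872 distinct seeds (665 unique, 207
shared), with 136 seeds shared by exactly two miRNAs of which 47 are
same-family (34.6%). These files are not bundled; obtain them from a
miRBase release archive.
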