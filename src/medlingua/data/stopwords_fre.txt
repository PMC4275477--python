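# Small French stop-word list (function words only); forms are normalized
# before use, so accents here are cosmetic.
le
la
les
un
une
des
de
du
au
aux
et
ou
en
dans
sur
sous
pour
par
avec
sans
ce
cette
ces
son
sa
ses
est
sont
a
à
il
elle
on
ne
pas
que
qui
dont
où
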