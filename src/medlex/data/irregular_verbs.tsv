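# Irregular-verb exception table: lemma <TAB> cell <TAB> surface
# cell is mood.tense.PN (PN in 1s 2s 3s 1p 2p 3p) or gerund / participle.
# Only cells where the regular -ar/-er/-ir paradigm fails are listed.
doler	indicative.present.1s	duelo
doler	indicative.present.2s	dueles
doler	indicative.present.3s	duele
doler	indicative.present.3p	duelen
doler	subjunctive.present.1s	duela
doler	subjunctive.present.2s	duelas
doler	subjunctive.present.3s	duela
doler	subjunctive.present.3p	duelan
morir	indicative.present.1s	muero
morir	indicative.present.2s	mueres
morir	indicative.present.3s	muere
morir	indicative.present.3p	mueren
morir	indicative.past.3s	murió
morir	indicative.past.3p	murieron
morir	subjunctive.present.1s	muera
morir	subjunctive.present.2s	mueras
morir	subjunctive.present.3s	muera
morir	subjunctive.present.1p	muramos
morir	subjunctive.present.2p	muráis
morir	subjunctive.present.3p	mueran
morir	gerund	muriendo
morir	participle	muerto
sentir	indicative.present.1s	siento
sentir	indicative.present.2s	sientes
sentir	indicative.present.3s	siente
sentir	indicative.present.3p	sienten
sentir	indicative.past.3s	sintió
sentir	indicative.past.3p	sintieron
sentir	subjunctive.present.1s	sienta
sentir	subjunctive.present.2s	sientas
sentir	subjunctive.present.3s	sienta
sentir	subjunctive.present.1p	sintamos
sentir	subjunctive.present.2p	sintáis
sentir	subjunctive.present.3p	sientan
sentir	gerund	sintiendo
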