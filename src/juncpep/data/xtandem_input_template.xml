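<?xml version="1.0"?>
<!--
  X!Tandem input template for junction-peptide database searches.
  Documentation only: this package never executes the engine.

  The one deviation from engine defaults is the parent monoisotopic
  mass window, tightened to +/- 10 Da; all other parameters follow the
  engine's default_input.xml.
-->
<bioml>
  <note type="input" label="spectrum, parent monoisotopic mass error plus">10.0</note>
  <note type="input" label="spectrum, parent monoisotopic mass error minus">10.0</note>
  <note type="input" label="spectrum, parent monoisotopic mass error units">Daltons</note>
  <note type="input" label="protein, cleavage site">[RK]|{P}</note>
  <note type="input" label="scoring, maximum missed cleavage sites">2</note>
  <note type="input" label="list path, default parameters">default_input.xml</note>
  <note type="input" label="protein, taxon">other mammals</note>
  <note type="input" label="spectrum, path">REPLACE_WITH_MGF</note>
  <note type="input" label="output, path">output.xml</note>
</bioml>
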