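<?xml version="1.0" encoding="UTF-8"?>
<!-- Mass-action form of the package's built-in E-cadherin/beta-catenin
     network.  The free proteasome is an explicit species here (Proteasome),
     so every rate is a plain product; the built-in definition tracks only
     the bound form and implies Proteasome = P0 - BcatPro.
     phi / psi are the contact-driven translocation signals (set per step by
     the coupling layer); d_eff is the complex dissociation rate including
     any detachment boost. -->
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="EcadBcatKinetics" name="E-cadherin/beta-catenin kinetics">
    <listOfCompartments>
      <compartment id="cell" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="Ecad" compartment="cell" initialConcentration="1.0"/>
      <species id="Bcat" compartment="cell" initialConcentration="0.0"/>
      <species id="Complex" compartment="cell" initialConcentration="0.0"/>
      <species id="BcatPro" compartment="cell" initialConcentration="0.0"/>
      <species id="Proteasome" compartment="cell" initialConcentration="1.0"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k1" value="20.0"/>
      <parameter id="phi" value="0.0"/>
      <parameter id="psi" value="0.0"/>
      <parameter id="d_eff" value="0.2"/>
      <parameter id="kappa" value="5.0"/>
      <parameter id="k_minus" value="0.1"/>
      <parameter id="nu" value="0.4"/>
      <parameter id="alpha" value="0.1"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="complex_formation" reversible="false">
        <listOfReactants>
          <speciesReference species="Ecad"/>
          <speciesReference species="Bcat"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="Complex"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>k1</ci><ci>phi</ci><ci>Ecad</ci><ci>Bcat</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="complex_dissociation" reversible="false">
        <listOfReactants>
          <speciesReference species="Complex"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="Ecad"/>
          <speciesReference species="Bcat"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>d_eff</ci><ci>Complex</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="contact_loss_release" reversible="false">
        <listOfReactants>
          <speciesReference species="Complex"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="Ecad"/>
          <speciesReference species="Bcat"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>psi</ci><ci>Complex</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="proteasome_binding" reversible="false">
        <listOfReactants>
          <speciesReference species="Bcat"/>
          <speciesReference species="Proteasome"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="BcatPro"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>kappa</ci><ci>Bcat</ci><ci>Proteasome</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="proteasome_unbinding" reversible="false">
        <listOfReactants>
          <speciesReference species="BcatPro"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="Bcat"/>
          <speciesReference species="Proteasome"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>k_minus</ci><ci>BcatPro</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="bcat_degradation" reversible="false">
        <listOfReactants>
          <speciesReference species="BcatPro"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="Proteasome"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>nu</ci><ci>BcatPro</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="bcat_production" reversible="false">
        <listOfProducts>
          <speciesReference species="Bcat"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <ci>alpha</ci>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
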