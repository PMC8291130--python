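<Simulation>
<Variable Name="SIM_TIME">0.6</Variable>
<Variable Name="INPUT_RATE">1000</Variable>
<WeightType>CustomConnectionParameters</WeightType>
<Algorithms>
  <Algorithm type="GridAlgorithm" name="COND"
             modelfile="cond.model" tmatfile="cond.tmat"
             tau_refractive="0.002"/>
  <Algorithm type="RateAlgorithm" name="ExcitatoryInput">
    <rate>INPUT_RATE</rate>
  </Algorithm>
</Algorithms>
<Nodes>
  <Node algorithm="COND" name="E" type="EXCITATORY"/>
  <Node algorithm="COND" name="I" type="INHIBITORY"/>
  <Node algorithm="ExcitatoryInput" name="InE" type="EXCITATORY"/>
  <Node algorithm="ExcitatoryInput" name="InI" type="EXCITATORY"/>
</Nodes>
<Connections>
  <Connection In="InE" Out="E" num_connections="1" efficacy="0.05" delay="0"/>
  <Connection In="InI" Out="I" num_connections="1" efficacy="0.05" delay="0"/>
  <Connection In="E" Out="I" num_connections="5" efficacy="0.05"
              delay="0.001"/>
  <Connection In="I" Out="E" num_connections="5" efficacy="-0.05"
              delay="0.001"/>
  <Connection In="E" Out="E" num_connections="2" efficacy="0.05"
              delay="0.001"/>
  <Connection In="I" Out="I" num_connections="2" efficacy="-0.05"
              delay="0.001"/>
</Connections>
<Reporting>
  <Rate node="E" t_interval="0.001"/>
  <Rate node="I" t_interval="0.001"/>
  <Density node="E" t_start="0.0" t_end="0.6" t_interval="0.1"/>
</Reporting>
<SimulationRunParameter>
  <SimulationName>cond</SimulationName>
  <t_end>SIM_TIME</t_end>
  <t_step>0.001</t_step>
  <name_log>cond.log</name_log>
  <master_steps>10</master_steps>
</SimulationRunParameter>
</Simulation>
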