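food,code
fried rice,O010301# F07.1$ F07.4$ F07.5$ F07.6$ F07.8$ F07.14
sushi,O010302# F07.1$ F07.4$ F07.6$ F07.8$ F07.9$ F07.14
rice ball,O010303# F07.1$ F07.4$ F07.6$ F07.8$ F07.14
fried rice (compact),O010301#F07.1$F07.4$F07.5$F07.6$F07.8$F07.14
pizza,O0206# F07.1$ F07.4$ F07.6$ F07.8
white rice (legacy facet),A010101#F01.1
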