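name,sub_code
rice,1
flour,1
noodles,1
water,2
tofu,3
soybean,3
anchovy larvae,4
salmon,4
swordfish,4
tuna,4
shrimp,4
egg,5
pork,6
beef,6
chicken,6
milk,7
sweet pepper,8
cabbage,8
cucumber,8
tomato,8
lettuce,8
carrot,8
scallion,8
avocado,9
peanut,10
sesame,10
sesame oil,11
lard,11
vegetable oil,11
tea,12
rice wine,13
salt,14
soy sauce,14
salt soy sauce,14
mustard,14
sugar,14
pepper,14
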