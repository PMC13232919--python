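# Neutral everyday vocabulary for synthetic background text. Content-safe by
# construction: no clinical or distress vocabulary appears here.
morning
coffee
kitchen
window
garden
bicycle
weather
sunshine
library
notebook
pencil
lecture
homework
weekend
grocery
market
recipe
dinner
breakfast
sandwich
orange
apple
banana
guitar
piano
melody
concert
movie
theater
novel
chapter
puzzle
chess
soccer
basketball
running
hiking
mountain
river
forest
beach
ocean
island
airport
luggage
ticket
journey
holiday
camera
photograph
painting
museum
gallery
sculpture
pottery
knitting
sweater
jacket
umbrella
raincoat
autumn
winter
spring
summer
harvest
festival
parade
neighbor
village
city
street
bridge
station
train
subway
traffic
bakery
chocolate
vanilla
caramel
lemonade
picnic
blanket
candle
lantern
bookshelf
ladder
toolbox
hammer
garden
tomato
carrot
potato
pepper
basil
rosemary
kitten
puppy
parrot
goldfish
turtle
meadow
willow
maple
acorn
pebble
seashell
kite
balloon
carousel
circus
juggler
magician
violin
trumpet
drummer
chorus
ballad
poetry
author
editor
printer
envelope
postcard
stamp
parcel
calendar
schedule
meeting
project
keyboard
monitor
charger
battery
flashlight
compass
backpack
canteen
campfire
marshmallow
constellation
telescope
microscope
laboratory
experiment
magnet
circuit
gearbox
engine
propeller
sailboat
harbor
lighthouse
anchor
fisherman
seagull
dolphin
coral
lagoon
waterfall
canyon
plateau
prairie
orchard
vineyard
barrel
cellar
attic
porch
hallway
staircase
carpet
curtain
cushion
teapot
saucer
spoon
whisk
oven
skillet
casserole
noodle
dumpling
pretzel
muffin
bagel
yogurt
granola
almond
walnut
raisin
clementine
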